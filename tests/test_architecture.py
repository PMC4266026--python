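"""Structure: construction, wiring counts, persistence, serialization."""

import numpy as np
import pytest

import sdcmem as m


def study2_config():
    """24x24 input; L1 4x4 macs Q=9 K=16; L2 2x2 macs Q=9 K=9; L3 1 mac Q=9 K=9."""
    return m.ModelConfig(
        input_grid=(24, 24),
        levels=[
            m.LevelConfig(grid=(4, 4), q=9, k=16, delta=1, pi_u=(5, 7)),
            m.LevelConfig(grid=(2, 2), q=9, k=9, delta=2, pi_u=(1, 4)),
            m.LevelConfig(grid=(1, 1), q=9, k=9, delta=4, pi_u=(1, 4)),
        ])


def test_single_mac_unit_count():
    net = m.build_network(m.single_mac_config(q=9, k=4, pi_u=(9, 12)))
    assert m.count_units(net) == 144 + 36


def test_multilevel_unit_and_mac_count():
    net = m.build_network(study2_config())
    assert len(net.macs) == 21
    assert m.count_units(net) == 576 + 16 * 144 + 4 * 81 + 81 == 3285


@pytest.mark.parametrize("k,expected", [
    (4, 6336), (8, 14976), (12, 25920), (16, 39168), (32, 115200)])
def test_single_mac_weight_counts_closed_form(k, expected):
    # brute-force oracle: full U (P*Z) plus H over all cross-CM cell pairs
    p, q = 144, 9
    z = q * k
    oracle = p * z + sum(1 for j in range(z) for i in range(z)
                         if j // k != i // k)
    assert oracle == p * z + z * (z - k) == expected
    net = m.build_network(m.single_mac_config(q=q, k=k, pi_u=(9, 12)))
    counts = m.count_weights(net)
    assert counts["total"] == expected
    assert counts["U"] == p * z and counts["H"] == z * (z - k)


def test_h_wiring_own_cm_inclusion_switch():
    cfg = m.single_mac_config(q=9, k=4, pi_u=(9, 12), h_include_own_cm=True)
    counts = m.count_weights(m.build_network(cfg))
    assert counts["H"] == 36 * 36  # full same-mac recurrence


def test_rf_atomicity_all_cells_share_rfs():
    net = m.build_network(study2_config())
    for mac in net.macs.values():
        for proj in mac.projections():
            # every cell sees the same presynaptic source set
            srcs = [b.mac_id or "pixels" for b in proj.blocks]
            assert len(srcs) == len(set(srcs))
            if proj.kind != "H":
                assert proj.mask.all()


def test_build_determinism():
    a = m.build_network(study2_config())
    b = m.build_network(study2_config())
    assert a.order == b.order
    for mid in a.order:
        for pa, pb in zip(a.macs[mid].projections(),
                          b.macs[mid].projections()):
            assert pa.n_pre == pb.n_pre
            assert np.array_equal(pa.mask, pb.mask)
            assert np.array_equal(pa.sigma, pb.sigma)


def test_blank_network_weights_zero():
    net = m.build_network(m.single_mac_config(q=9, k=4, pi_u=(9, 12)))
    for proj in net.macs[(1, 0, 0)].projections():
        assert not proj.weights(net.wtable).any()


def test_inconsistent_tiling_rejected():
    cfg = m.ModelConfig(input_grid=(10, 10), levels=[
        m.LevelConfig(grid=(3, 3), q=4, k=4, delta=1, pi_u=(1, 5))])
    with pytest.raises(m.ConfigurationError):
        m.build_network(cfg)


def test_zero_levels_rejected():
    with pytest.raises(m.ConfigurationError):
        m.ModelConfig(input_grid=(12, 12), levels=[])


def test_decreasing_persistence_rejected():
    with pytest.raises(m.ConfigurationError):
        m.ModelConfig(input_grid=(24, 24), levels=[
            m.LevelConfig(grid=(2, 2), q=4, k=4, delta=2, pi_u=(1, 9)),
            m.LevelConfig(grid=(1, 1), q=4, k=4, delta=1, pi_u=(1, 4))])


def test_persistence_tick_holds_and_expires():
    net = m.build_network(study2_config())
    l2 = net.macs[(2, 0, 0)]        # delta = 2
    l2.code = np.arange(0, 81, 9)
    l2.code_age = 0
    assert (2, 0, 0) in m.tick_persistence(net)   # age 1 < 2: persists
    assert l2.code_age == 1
    assert (2, 0, 0) not in m.tick_persistence(net)  # age 2: expired
    l1 = net.macs[(1, 0, 0)]        # delta = 1: eligible every frame
    l1.code = np.arange(0, 144, 16)
    l1.code_age = 0
    assert (1, 0, 0) not in m.tick_persistence(net)


def test_per_mac_rng_substreams_independent_of_order():
    net = m.build_network(study2_config())
    net.reset_state(5)
    draws = {mid: net.macs[mid].rng.integers(1 << 30) for mid in net.order}
    net.reset_state(5)
    for mid in reversed(net.order):
        assert net.macs[mid].rng.integers(1 << 30) == draws[mid]


def test_state_roundtrip_h5(tmp_path):
    net = m.build_network(m.single_mac_config(q=9, k=4, pi_u=(9, 12)))
    net.reset_state(3)
    seq = m.gen_random_sequences(1, 5, (12, 12), (9, 12), seed=4)[0]
    m.train_sequence(net, seq.to_dense())
    path = str(tmp_path / "state.h5")
    net.save(path)
    loaded = m.Network.load(path)
    for mid in net.order:
        for pa, pb in zip(net.macs[mid].projections(),
                          loaded.macs[mid].projections()):
            assert np.array_equal(pa.sigma, pb.sigma)
            assert np.array_equal(pa.theta, pb.theta)
    assert loaded.config.to_dict() == net.config.to_dict()


def test_config_yaml_roundtrip():
    cfg = study2_config()
    again = m.ModelConfig.from_yaml(cfg.to_yaml())
    assert again.to_dict() == cfg.to_dict()
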