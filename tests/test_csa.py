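"""Code selection: each step's arithmetic plus the orchestrated contracts."""

import numpy as np
import pytest

import sdcmem as m
from sdcmem.csa import hard_max_winners, select_variant

PARAMS = m.CSAParams()


# ------------------------------------------------------------------ step 1

def test_gate_by_feature_bounds():
    assert m.gate_mac(code_age=0, delta=1, has_code=False, pi_u=6, bounds=(5, 7))
    assert not m.gate_mac(code_age=2, delta=2, has_code=True, pi_u=8, bounds=(5, 7))
    # persistence trumps the bounds
    assert m.gate_mac(code_age=1, delta=2, has_code=True, pi_u=0, bounds=(5, 7))


# -------------------------------------------------------------- steps 2-3

def _blank_mac(q=9, k=4, pi_u=(5, 7)):
    net = m.build_network(m.single_mac_config(q=q, k=k, pi_u=pi_u))
    return net, net.macs[(1, 0, 0)]


def test_raw_summation_forced_arithmetic():
    # 6 active pixels, all weights at 127 -> u = 762 on every cell
    net, mac = _blank_mac()
    mac.u_proj.sigma[...] = 0
    pre = np.zeros(144)
    pre[:6] = 1
    from sdcmem.csa import MacFrameState, raw_summations
    st = MacFrameState(t=0, mode="learning")
    raw_summations(mac, m.MacInputs(t=0, pre_u=pre, pi_u=6, pi_u_star=6),
                   net.wtable, st)
    assert (st.u == 6 * 127).all()


def test_raw_summation_mch_weighted_h():
    # a previous full-code match over 8 reachable H synapses at 127, source
    # mac reporting two competing hypotheses: h = 8 * 127 * 2**0.7
    net, mac = _blank_mac()
    mac.h_proj.sigma[...] = 0
    code = np.arange(0, 36, 4)  # one cell per CM
    act = np.zeros(36)
    act[code] = 2 ** 0.7
    from sdcmem.csa import MacFrameState, raw_summations
    st = MacFrameState(t=1, mode="learning")
    raw_summations(mac, m.MacInputs(t=1, pre_h=act, h_feat=1, h_reach_sum=8),
                   net.wtable, st)
    assert st.h[code[0]] == pytest.approx(8 * 127 * 2 ** 0.7)  # ~1650.5
    assert st.h[code[0]] == pytest.approx(1650.5, abs=0.1)


def test_normalization_clamps_to_one():
    net, mac = _blank_mac(pi_u=(5, 7))
    from sdcmem.csa import MacFrameState, normalize_inputs
    st = MacFrameState(t=0, mode="learning")
    st.u = np.full(36, 762.0)   # 762 / (5*127) = 1.2 -> clamp
    normalize_inputs(mac, m.MacInputs(t=0, pre_u=np.ones(144), pi_u=6,
                                      pi_u_star=6), PARAMS, st)
    assert (st.U == 1.0).all()
    st2 = MacFrameState(t=0, mode="learning")
    st2.u = np.zeros(36)
    normalize_inputs(mac, m.MacInputs(t=0, pre_u=np.zeros(144), pi_u=6,
                                      pi_u_star=6), PARAMS, st2)
    assert (st2.U == 0.0).all()


def test_normalization_upper_level_denominator():
    # L>=1 mac fed by macs: denominator min(pi_lo, pi*) * Q_src * w_max
    cfg = m.ModelConfig(input_grid=(12, 12), levels=[
        m.LevelConfig(grid=(2, 2), q=9, k=4, delta=1, pi_u=(9, 36)),
        m.LevelConfig(grid=(1, 1), q=9, k=4, delta=2, pi_u=(1, 4))])
    net = m.build_network(cfg)
    mac = net.macs[(2, 0, 0)]
    from sdcmem.csa import MacFrameState, normalize_inputs
    st = MacFrameState(t=0, mode="learning")
    st.u = np.full(36, 1143.0)  # = 1 * 9 * 127
    normalize_inputs(mac, m.MacInputs(t=0, pre_u=np.ones(144), pi_u=2,
                                      pi_u_star=2, u_reach=9), PARAMS, st)
    assert st.U == pytest.approx(1.0)


# -------------------------------------------------------------- steps 4-8

def test_local_support_products():
    one = np.ones(4)
    assert (m.local_support(one, one, one, 1, PARAMS) == 1).all()
    assert (m.local_support(one, np.zeros(4), one, 1, PARAMS) == 0).all()
    assert m.local_support(np.full(4, 0.8), None, None, 0, PARAMS)[0] == \
        pytest.approx(0.8)


def test_count_mch_round_to_nearest():
    # zeta_q = (3,2,2,2) -> mean 2.25 -> 2
    V = np.zeros((4, 4))
    V[0, :3] = 1.0
    V[1:, :2] = 1.0
    zq, z = m.count_mch(V.reshape(-1), 4, 4, PARAMS)
    assert list(zq) == [3, 2, 2, 2] and z == 2
    # two tied codes everywhere -> zeta = 2
    V2 = np.zeros((4, 4))
    V2[:, :2] = 1.0
    assert m.count_mch(V2.reshape(-1), 4, 4, PARAMS)[1] == 2
    # active mac floor: all-zero support still counts its own hypothesis
    assert m.count_mch(np.zeros(16), 4, 4, PARAMS)[1] == 1


def test_mch_factor_boost_and_cutoff():
    assert m.mch_factor(1, PARAMS) == 1.0
    assert m.mch_factor(2, PARAMS) == pytest.approx(2 ** 0.7)
    assert m.mch_factor(5, PARAMS) == 0.0          # muddled beyond B=4
    off = m.CSAParams(mch_enabled=False)
    assert m.mch_factor(5, off) == 1.0


def test_cm_hard_max_keeps_ties():
    V = np.array([0.2, 0.9, 0.4, 1.0, 1.0, 0.3])
    v_hat, argmax = m.cm_hard_max(V, 2, 3)
    assert list(v_hat) == [0.9, 1.0]
    assert list(argmax[0]) == [1] and list(argmax[1]) == [0, 1]
    v0, a0 = m.cm_hard_max(np.zeros(3), 1, 3)
    assert v0[0] == 0 and list(a0[0]) == [0, 1, 2]


def test_familiarity_is_mean_of_cm_maxima():
    assert m.familiarity_G(np.array([1.0, 1.0, 0.5, 0.5])) == 0.75
    assert m.familiarity_G(np.ones(9)) == 1.0
    assert m.familiarity_G(np.zeros(9)) == 0.0


# ------------------------------------------------------------- steps 9-12

def test_sigmoid_range_examples():
    assert m.sigmoid_range(0.0, 4, PARAMS) == 1.0
    assert m.sigmoid_range(1.0, 4, PARAMS) == 1.0 + 100 * 4
    p = m.CSAParams(g_floor=0.2, chi=25.0)
    assert m.sigmoid_range(0.6, 4, p) == pytest.approx(1 + 0.25 * 100)
    assert m.sigmoid_range(0.1, 4, p) == 1.0  # below the floor


def test_v_to_psi_shape():
    eta = 11.0
    psi = m.v_to_psi(np.array([0.5]), eta, PARAMS)
    assert psi[0] == pytest.approx((eta + 1) / 2)   # logistic midpoint
    assert (m.v_to_psi(np.linspace(0, 1, 5), 1.0, PARAMS) == 1.0).all()
    hi = m.v_to_psi(np.array([1.0]), eta, m.CSAParams(sigma2=100.0))
    assert hi[0] == pytest.approx(eta, abs=1e-3)


def test_psi_to_rho_normalizes_per_cm():
    rho = m.psi_to_rho(np.ones(8), 2, 4)
    assert (rho == 0.25).all()
    rho2 = m.psi_to_rho(np.array([300.0, 1, 1, 1, 1, 1, 1]), 1, 7)
    assert rho2[0] == pytest.approx(300 / 306)
    rho3 = m.psi_to_rho(np.array([30.0, 1, 1, 1, 1, 1, 1]), 1, 7)
    assert rho3[0] == pytest.approx(30 / 36)
    assert rho2.sum() == pytest.approx(1.0, abs=1e-12)


def test_draw_winners_follows_rho():
    rng = np.random.default_rng(0)
    onehot = np.zeros(8)
    onehot[[2, 5]] = 1.0
    for _ in range(5):
        assert list(m.draw_winners(onehot, 2, 4, rng)) == [2, 5]
    # uniform: empirical frequencies approx 1/K within binomial error
    rho = np.full(4, 0.25)
    counts = np.zeros(4)
    n = 8000
    for _ in range(n):
        counts[m.draw_winners(rho, 1, 4, rng)[0]] += 1
    se = np.sqrt(n * 0.25 * 0.75)
    assert (np.abs(counts - n / 4) < 4 * se).all()
    # reproducibility
    a = m.draw_winners(np.full(8, 0.25), 2, 4, np.random.default_rng(9))
    b = m.draw_winners(np.full(8, 0.25), 2, 4, np.random.default_rng(9))
    assert list(a) == list(b)


def test_hard_max_tie_break_is_seeded():
    v_hat = np.array([1.0])
    ties = [np.array([0, 2])]
    a = hard_max_winners(v_hat, ties, 4, np.random.default_rng(3))
    b = hard_max_winners(v_hat, ties, 4, np.random.default_rng(3))
    assert list(a) == list(b) and a[0] in (0, 2)


# ----------------------------------------------------------- orchestration

def _inputs_for(net, mac, pixels, t, prev):
    from sdcmem.engine import _build_inputs
    return _build_inputs(net, mac, pixels, t, prev)


def test_csa_step_blank_network_is_uniform():
    net, mac = _blank_mac(pi_u=(9, 12))
    net.reset_state(2)
    frame = np.zeros(144, dtype=np.int8)
    frame[:10] = 1
    code, st = m.csa_step(mac, _inputs_for(net, mac, frame, 0, {}),
                          "learning", PARAMS, net.config.backoff, net.wtable)
    assert st.G == 0.0 and st.eta == 1.0
    assert (st.rho == 1.0 / mac.k).all()
    assert len(code) == mac.q


def test_csa_step_sum_rho_per_cm_is_one():
    net, mac = _blank_mac(pi_u=(9, 12))
    net.reset_state(2)
    seq = m.gen_random_sequences(1, 5, (12, 12), (9, 12), seed=8)[0]
    m.train_sequence(net, seq.to_dense())
    frame = seq.to_dense()[0]
    _, st = m.csa_step(mac, _inputs_for(net, mac, frame, 0, {}),
                       "probabilistic", PARAMS, net.config.backoff, net.wtable)
    sums = st.rho.reshape(mac.q, mac.k).sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_csa_step_fixed_operation_count():
    counts = []
    for n_codes in (1, 50):
        net, mac = _blank_mac(q=9, k=8, pi_u=(9, 12))
        net.reset_state(4)
        seqs = m.gen_random_sequences(n_codes, 1, (12, 12), (9, 12), seed=6)
        m.train(net, [s.to_dense() for s in seqs])
        frame = seqs[0].to_dense()[0]
        _, st = m.csa_step(mac, _inputs_for(net, mac, frame, 0, {}),
                           "learning", PARAMS, net.config.backoff, net.wtable)
        counts.append(st.op_count)
    assert counts[0] == counts[1]


def test_csa_step_exact_repeat_simple_mode_reinstates():
    net, mac = _blank_mac(pi_u=(9, 12))
    net.reset_state(2)
    seq = m.gen_random_sequences(1, 1, (12, 12), (9, 12), seed=8)[0]
    trace = m.train_sequence(net, seq.to_dense())
    stored = trace[0][(1, 0, 0)].code
    code, st = m.csa_step(mac, _inputs_for(net, mac, seq.to_dense()[0], 0, {}),
                          "simple", PARAMS, net.config.backoff, net.wtable)
    assert list(code) == stored and st.G == pytest.approx(1.0)


def test_unknown_mode_rejected():
    net, mac = _blank_mac(pi_u=(9, 12))
    frame = np.zeros(144, dtype=np.int8)
    frame[:10] = 1
    with pytest.raises(ValueError):
        m.csa_step(mac, _inputs_for(net, mac, frame, 0, {}), "banana",
                   PARAMS, net.config.backoff, net.wtable)
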