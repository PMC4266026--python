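"""Plasticity: correlation, aging, permanence, saturation and freezing."""

import numpy as np
import pytest

import sdcmem as m
from sdcmem.plasticity import age_tick, apply_correlation, check_freeze


def _net(q=9, k=4, pi_u=(9, 12)):
    net = m.build_network(m.single_mac_config(q=q, k=k, pi_u=pi_u))
    net.reset_state(1)
    return net, net.macs[(1, 0, 0)]


def _pre_post(mac, n_pre_active=6):
    pre = np.zeros(mac.u_proj.n_pre, dtype=bool)
    pre[:n_pre_active] = True
    post = np.zeros(mac.z, dtype=bool)
    post[np.arange(0, mac.z, mac.k)] = True   # one cell per CM
    return pre, post


def test_first_correlation_sets_weight_max_without_permanence():
    net, mac = _net()
    pre, post = _pre_post(mac)
    apply_correlation(mac.u_proj, pre, post, net.wtable)
    corr = pre[:, None] & post[None, :]
    assert (mac.u_proj.sigma[corr] == 0).all()
    assert (mac.u_proj.theta[corr] == 0).all()        # blank state: no repeat
    assert (mac.u_proj.weights(net.wtable)[corr] == 127).all()
    assert (mac.u_proj.sigma[~corr] == net.wtable.sigma_max).all()


def test_repeat_correlation_within_window_increments_permanence():
    net, mac = _net()
    pre, post = _pre_post(mac)
    apply_correlation(mac.u_proj, pre, post, net.wtable)
    age_tick(mac.u_proj, net.wtable)
    apply_correlation(mac.u_proj, pre, post, net.wtable)   # sigma=1 <= T(0)
    corr = pre[:, None] & post[None, :]
    assert (mac.u_proj.theta[corr] == 1).all()


def test_repeat_correlation_after_window_resets_age_only():
    net, mac = _net()
    pre, post = _pre_post(mac)
    apply_correlation(mac.u_proj, pre, post, net.wtable)
    for _ in range(int(net.wtable.window(0)) + 1):   # age past T(0)
        age_tick(mac.u_proj, net.wtable)
    apply_correlation(mac.u_proj, pre, post, net.wtable)
    corr = pre[:, None] & post[None, :]
    assert (mac.u_proj.theta[corr] == 0).all()
    assert (mac.u_proj.sigma[corr] == 0).all()


def test_age_tick_caps_and_pins():
    net, mac = _net()
    proj = mac.u_proj
    proj.sigma[...] = net.wtable.sigma_max
    age_tick(proj, net.wtable)
    assert (proj.sigma == net.wtable.sigma_max).all()    # capped
    proj.theta[0, 0] = net.wtable.theta_max
    age_tick(proj, net.wtable)
    assert proj.sigma[0, 0] == 0                          # pinned young
    assert proj.weights(net.wtable)[0, 0] == 127


def test_weight_decays_after_plateau():
    net, mac = _net()
    pre, post = _pre_post(mac)
    apply_correlation(mac.u_proj, pre, post, net.wtable)
    corr = pre[:, None] & post[None, :]
    t_w = int(net.wtable.window(0))
    for _ in range(t_w):
        age_tick(mac.u_proj, net.wtable)
    assert (mac.u_proj.weights(net.wtable)[corr] == 127).all()   # plateau edge
    for _ in range(t_w // 2):
        age_tick(mac.u_proj, net.wtable)
    w = mac.u_proj.weights(net.wtable)[corr]
    assert (0 < w).all() and (w < 127).all()                      # mid-decay
    for _ in range(t_w):
        age_tick(mac.u_proj, net.wtable)
    assert (mac.u_proj.weights(net.wtable)[corr] == 0).all()      # fully decayed


def test_saturation_direct_count():
    net, mac = _net()
    pre, post = _pre_post(mac, n_pre_active=6)
    apply_correlation(mac.u_proj, pre, post, net.wtable)
    # 6 pixels x 9 winners potentiated of 144*36 synapses
    assert mac.u_proj.saturation(net.wtable) == pytest.approx(54 / 5184)
    blank = m.build_network(m.single_mac_config(q=9, k=4, pi_u=(9, 12)))
    assert blank.macs[(1, 0, 0)].u_proj.saturation(blank.wtable) == 0.0


def test_freeze_any_matrix_rule_and_irreversibility():
    net, mac = _net()
    mac.h_proj.sigma[...] = 0          # saturate H fully
    assert check_freeze(net) == [(1, 0, 0)]
    assert mac.frozen and all(p.frozen for p in mac.projections())
    assert check_freeze(net) == []     # already frozen: no new events


def test_frozen_mac_weights_immutable_under_training():
    net, mac = _net()
    mac.frozen = True
    for p in mac.projections():
        p.frozen = True
    before = {p.kind: (p.sigma.copy(), p.theta.copy())
              for p in mac.projections()}
    seqs = m.gen_random_sequences(3, 10, (12, 12), (9, 12), seed=5)
    m.train(net, [s.to_dense() for s in seqs])
    for p in mac.projections():
        sig, th = before[p.kind]
        assert np.array_equal(p.sigma, sig)
        assert np.array_equal(p.theta, th)


def test_correlation_respects_h_mask():
    net, mac = _net()
    pre = np.zeros(mac.z, dtype=bool)
    pre[0] = True                      # a cell in CM 0
    post = np.zeros(mac.z, dtype=bool)
    post[1] = True                     # another cell of the same CM
    apply_correlation(mac.h_proj, pre, post, net.wtable)
    assert mac.h_proj.sigma[0, 1] == net.wtable.sigma_max   # masked pair


def test_permanence_never_decreases_during_training():
    net, mac = _net()
    seqs = m.gen_random_sequences(2, 10, (12, 12), (9, 12), seed=9)
    prev_theta = {p.kind: p.theta.copy() for p in mac.projections()}
    for s in seqs:
        m.train_sequence(net, s.to_dense())
        for p in mac.projections():
            assert (p.theta >= prev_theta[p.kind]).all()
            prev_theta[p.kind] = p.theta.copy()
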