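"""Study-style benchmark drivers built from the library primitives.

Each driver runs many seeded replicates of a small, fully synthetic
protocol and reports averaged statistics:

* :func:`bench_study3` — noisy best-match retrieval: train a blank
  single-mac model on random 10-frame sequences (one trial each), test
  pixel-relocated versions in simple retrieval mode with back-off, report
  mean whole-trace accuracy R* and final-frame accuracy R-omega.
* :func:`bench_sisc` — similar-inputs-similar-codes: an overlap ladder of
  2-frame sequences sharing their second frame; the second-frame codes'
  intersection with the reference code should fall as first-frame overlap
  falls.
* :func:`bench_mch` — multiple-competing-hypotheses disambiguation: after
  storing [A,B,C] and [D,B,E], prompting with [B,C] should reinstate the
  [A,B,C] context code at frame 2, more reliably with the MCH boost on
  than off.
* :func:`warp_demo` — time-warp catch-up: a two-level model that stored a
  4-frame sequence recognizes the 3-frame deletion variant, its internal
  state re-locking onto the shifted learning trace via back-off.

All drivers derive per-replicate seeds from one master seed and are fully
reproducible.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .architecture import build_network
from .config import (BackoffPolicy, CSAParams, LevelConfig, ModelConfig,
                     single_mac_config)
from .engine import recognize_sequence, train
from .metrics import code_intersection, code_similarity, trace_accuracy
from .synthetic import (FrameSequence, gen_overlap_ladder,
                        gen_random_sequences, perturb_sequence, warp_sequence)


def _child_seeds(seed: int, n: int, per: int) -> list[list[int]]:
    """Deterministic per-replicate seed bundles (kept below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [[int(x) & 0x7FFFFFFF for x in child.generate_state(per)]
            for child in ss.spawn(n)]


# ------------------------------------------------------------- noisy recall

def bench_study3(k: int, s: int, noise_pixels: int, n_reps: int = 25,
                 seed: int = 0, q: int = 9, grid: tuple[int, int] = (12, 12),
                 n_frames: int = 10, active_range: tuple[int, int] = (9, 12),
                 mode: str = "simple") -> dict:
    """Noisy best-match retrieval benchmark (single-mac model).

    Per replicate: build a blank Q x K single-mac model, store ``s``
    random ``n_frames``-frame sequences in one trial each, relocate
    ``noise_pixels`` pixels per test frame, recognize in ``mode`` with
    back-off, and score R*/R-omega against the learning trace.  Returns
    means and standard deviations across replicates on the percent scale.
    """
    rep_r_star: list[float] = []
    rep_r_omega: list[float] = []
    for s_data, s_net, s_noise in _child_seeds(seed, n_reps, 3):
        cfg = single_mac_config(grid=grid, q=q, k=k, pi_u=active_range)
        net = build_network(cfg)
        net.reset_state(s_net)
        seqs = gen_random_sequences(s, n_frames, grid, active_range, s_data)
        learn_traces = train(net, [sq.to_dense() for sq in seqs])
        r_stars, r_omegas = [], []
        for i, sq in enumerate(seqs):
            noisy = perturb_sequence(sq, noise_pixels, s_noise + i)
            test = recognize_sequence(net, noisy.to_dense(), mode=mode)
            rep = trace_accuracy(learn_traces[i], test, label=sq.label)
            r_stars.append(rep.r_star)
            r_omegas.append(rep.r_omega)
        rep_r_star.append(100 * float(np.mean(r_stars)))
        rep_r_omega.append(100 * float(np.mean(r_omegas)))
    out = {"q": q, "k": k, "s": s, "noise_pixels": noise_pixels,
           "mode": mode, "n": n_reps}
    if n_reps:
        out.update(
            r_star_mean=round(float(np.mean(rep_r_star)), 1),
            r_star_sd=round(float(np.std(rep_r_star, ddof=1)), 1) if n_reps > 1 else 0.0,
            r_omega_mean=round(float(np.mean(rep_r_omega)), 1),
            r_omega_sd=round(float(np.std(rep_r_omega, ddof=1)), 1) if n_reps > 1 else 0.0,
            per_rep_r_star=[round(v, 2) for v in rep_r_star],
            per_rep_r_omega=[round(v, 2) for v in rep_r_omega],
        )
    return out


# -------------------------------------------------------------------- SISC

def bench_sisc(n_levels: int = 6, n_reps: int = 50, seed: int = 0,
               q: int = 25, k: int = 9, grid: tuple[int, int] = (12, 12),
               n_active: int = 12) -> dict:
    """Similar-inputs-to-similar-codes benchmark (overlap ladder).

    Trains each replicate's blank single-mac model on the ladder in order
    and measures the intersection of every second-frame code with the
    reference (ladder level 0) second-frame code.  Reports per-level mean
    intersections and a pooled Spearman correlation between ladder level
    (decreasing input overlap) and code intersection.
    """
    from scipy.stats import spearmanr

    mid = (1, 0, 0)
    inters = np.zeros((n_reps, n_levels))
    overlaps = np.zeros((n_reps, n_levels))
    for rep, (s_data, s_net) in enumerate(_child_seeds(seed, n_reps, 2)):
        cfg = single_mac_config(grid=grid, q=q, k=k,
                                pi_u=(n_active, n_active))
        net = build_network(cfg)
        net.reset_state(s_net)
        ladder, fracs = gen_overlap_ladder(grid, n_levels, s_data, n_active)
        traces = train(net, [sq.to_dense() for sq in ladder])
        ref = traces[0][1][mid].code
        for i, tr in enumerate(traces):
            inters[rep, i] = code_intersection(ref, tr[1][mid].code)
            overlaps[rep, i] = fracs[i]
    levels = np.tile(np.arange(n_levels), n_reps)
    rho, pval = spearmanr(levels, inters.reshape(-1))
    return {"q": q, "k": k, "n_levels": n_levels, "n": n_reps,
            "overlap_fractions": [round(float(v), 3)
                                  for v in overlaps.mean(axis=0)],
            "mean_intersection": [round(float(v), 2)
                                  for v in inters.mean(axis=0)],
            "spearman_rho": float(rho), "spearman_p": float(pval)}


# --------------------------------------------------------------------- MCH

def bench_mch(n_seeds: int = 100, seed: int = 0,
              grid: tuple[int, int] = (12, 12), q: int = 9, k: int = 8,
              n_active: int = 12) -> dict:
    """Ambiguous-prompt disambiguation with the MCH boost on vs off.

    Learn [A,B,C] and [D,B,E] (disjoint random items); prompt with [B,C]
    in probabilistic retrieval.  At the prompt's first frame both stored B
    codes tie (zeta = 2), so the chosen code is a mix; the boost F(zeta)
    amplifies its H signals, raising support for the correct [A,B,C]
    context code on the next frame.  Back-off is pinned to the H+U
    variant (threshold 0) so the comparison isolates the boost.
    Accuracy = similarity of the frame-2 code to the stored C-in-context
    code.
    """
    size = grid[0] * grid[1]
    if 5 * n_active > size:
        raise ValueError("five disjoint items do not fit the grid")
    mid = (1, 0, 0)
    gammas = {True: [], False: []}
    for s_net, s_items in _child_seeds(seed, n_seeds, 2):
        rng = np.random.default_rng(s_items)
        perm = rng.permutation(size)[: 5 * n_active].reshape(5, n_active)
        a, b, c, d, e = (np.sort(x) for x in perm)
        seq1 = FrameSequence(grid=grid, frames=[a, b, c], label="ABC")
        seq2 = FrameSequence(grid=grid, frames=[d, b, e], label="DBE")
        prompt = FrameSequence(grid=grid, frames=[b, c], label="BC")
        for boost in (True, False):
            cfg = single_mac_config(
                grid=grid, q=q, k=k, pi_u=(n_active, n_active),
                csa=CSAParams(mch_enabled=boost),
                backoff=BackoffPolicy(order=("HU", "U"),
                                      threshold_two_way=0.0))
            net = build_network(cfg)
            net.reset_state(s_net)
            traces = train(net, [seq1.to_dense(), seq2.to_dense()])
            target = traces[0][2][mid].code   # C in [A,B,C] context
            test = recognize_sequence(net, prompt.to_dense(),
                                      mode="probabilistic")
            gammas[boost].append(code_similarity(target, test[1][mid].code))
    return {"n": n_seeds, "q": q, "k": k,
            "boost_on_mean": float(np.mean(gammas[True])),
            "boost_off_mean": float(np.mean(gammas[False]))}


# -------------------------------------------------------------- time warp

def warp_demo_config(grid: tuple[int, int] = (12, 12)) -> ModelConfig:
    """Two-level model for the warp demo: level-2 codes persist 2 frames."""
    return ModelConfig(
        input_grid=grid,
        levels=[
            LevelConfig(grid=(1, 1), q=9, k=4, delta=1, pi_u=(12, 12),
                        h_radius=0),
            LevelConfig(grid=(1, 1), q=6, k=4, delta=2, pi_u=(1, 1),
                        h_radius=0),
        ])


def warp_demo(seed: int = 0, n_frames: int = 4,
              delete_pos: int = 1) -> dict:
    """Frame-deletion catch-up for a single stored hierarchical sequence.

    Stores one ``n_frames``-frame sequence; the deleted frame must be one
    covered by a persisting level-2 code so the top-down context bridges
    the gap.  Recognition (simple mode) of the shortened sequence should
    re-lock: from the frame after the deletion onward the full internal
    state equals the learning-trace state one frame ahead, and the final
    frame is recalled exactly.
    """
    grid = (12, 12)
    s_data, s_net = _child_seeds(seed, 1, 2)[0]
    cfg = warp_demo_config(grid)
    net = build_network(cfg)
    net.reset_state(s_net)
    seq = gen_random_sequences(1, n_frames, grid, (12, 12), s_data)[0]
    learn = train(net, [seq.to_dense()])[0]
    warped = warp_sequence(seq, {delete_pos: "delete"})
    test = recognize_sequence(net, warped.to_dense(), mode="simple")

    mids = list(net.macs)
    final_gamma = {
        str(m): code_similarity(learn[-1][m].code, test[-1][m].code)
        for m in mids}
    # after the deletion, test frame t should match learning frame t+1
    state_match = all(
        learn[t + 1][m].code == test[t][m].code
        for t in range(delete_pos, len(test)) for m in mids)
    return {"n_frames": n_frames, "delete_pos": delete_pos,
            "final_gamma": final_gamma, "state_match": bool(state_match),
            "learn_codes": [{str(m): learn[t][m].code for m in mids}
                            for t in range(len(learn))],
            "test_codes": [{str(m): test[t][m].code for m in mids}
                           for t in range(len(test))]}
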