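"""Frame-by-frame simulation: training and recognition drivers.

Each frame is processed bottom-up.  During learning, codes persist for
their level's delta frames (persistence trumps the activation gate), new
codes are drawn by the full CSA, and plasticity runs after the whole
network has updated.  During retrieval no weights change and no code is
held over: every mac re-selects its code on every frame from the current
evidence, which is what lets the memory re-lock onto a familiar sequence
at the right point after distortions such as time warping.

Temporal context (H and D evidence) always refers to the codes active on
the previous frame; same-level and top-down reads therefore come from a
snapshot taken at the end of frame t-1, while bottom-up reads use the
already-updated codes of the level below at frame t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .architecture import Mac, MacId, Network, tick_persistence
from .csa import (LEARNING, MODES, PROBABILISTIC, SIMPLE, MacInputs,
                  csa_step, mch_factor)
from .plasticity import plasticity_frame


@dataclass
class FrameRecord:
    """What one mac did on one frame (the unit of a trace)."""

    t: int
    mac_id: MacId
    active: bool
    persisted: bool = False
    code: Optional[list[int]] = None
    G: Optional[float] = None
    zeta: int = 0
    variant: str = ""
    mode: str = ""
    op_count: int = 0


#: A trace is one record per mac per frame.
Trace = list[dict[MacId, FrameRecord]]

# end-of-frame snapshot: mac id -> (binary activation over Z cells, F(zeta))
Snapshot = dict[MacId, tuple[np.ndarray, float]]


def _build_inputs(net: Network, mac: Mac, pixels: np.ndarray, t: int,
                  prev: Snapshot) -> MacInputs:
    """Assemble U/H/D presynaptic vectors and feature counts for one mac."""
    params = net.config.csa
    kw: dict = {"t": t}
    avail = {"U"}

    # U: current-frame pixels or current codes of the level below.
    up = mac.u_proj
    if up.blocks[0].kind == "pixels":
        pre = pixels[up.blocks[0].pixel_indices].astype(float)
        kw.update(pre_u=pre, pi_u=int(pre.sum()), pi_u_star=int(pre.sum()),
                  u_reach=0)
    else:
        pre = np.zeros(up.n_pre)
        pi_u = pi_star = 0
        for b in up.blocks:
            src = net.macs[b.mac_id]
            if not src.active:
                continue
            pi_u += 1
            f = mch_factor(src.zeta, params)
            if f > 0:
                pi_star += 1
                pre[b.sl] = src.cell_activation() * f
        kw.update(pre_u=pre, pi_u=pi_u, pi_u_star=pi_star,
                  u_reach=up.blocks[0].reachable)

    # H and D: previous-frame snapshot.
    for kind, proj in (("h", mac.h_proj), ("d", mac.d_proj)):
        if proj is None:
            continue
        pre = np.zeros(proj.n_pre)
        feat = 0
        reach_sum = 0
        for b in proj.blocks:
            entry = prev.get(b.mac_id)
            if entry is None:
                continue
            act, f = entry
            if f <= 0:   # muddled source: silent and uncounted
                continue
            pre[b.sl] = act * f
            feat += 1
            reach_sum += b.reachable
        if feat > 0:
            avail.add(kind.upper())
        kw.update({f"pre_{kind}": pre, f"{kind}_feat": feat,
                   f"{kind}_reach_sum": reach_sum})

    kw["available"] = frozenset(avail)
    return MacInputs(**kw)


def process_frame(net: Network, pixels: np.ndarray, t: int, mode: str,
                  learn: bool, persisting: set[MacId], prev: Snapshot
                  ) -> tuple[dict[MacId, FrameRecord], Snapshot]:
    """Run one frame bottom-up; apply plasticity if learning.

    Returns the per-mac records and the end-of-frame snapshot to feed the
    next frame's H/D context.
    """
    if learn and mode != LEARNING:
        raise ValueError(f"mode {mode!r} is retrieval-only; learning trials "
                         "must use the full probabilistic CSA")
    if not learn and mode == LEARNING:
        raise ValueError("learning mode requires plasticity enabled")
    params, policy = net.config.csa, net.config.backoff
    records: dict[MacId, FrameRecord] = {}
    corr_map: dict[tuple[MacId, str], tuple[np.ndarray, np.ndarray]] = {}

    for level in range(1, net.n_levels + 1):
        for mac in net.level_macs(level):
            mid = mac.id
            if learn and mid in persisting:
                # persistence trumps the activation gate: code held as-is
                records[mid] = FrameRecord(
                    t=t, mac_id=mid, active=True, persisted=True,
                    code=[int(c) for c in mac.code], zeta=mac.zeta, mode=mode)
                inputs = _build_inputs(net, mac, pixels, t, prev)
                _collect_correlations(mac, inputs, corr_map)
                continue
            inputs = _build_inputs(net, mac, pixels, t, prev)
            if not (mac.pi_u[0] <= inputs.pi_u <= mac.pi_u[1]):
                mac.clear()
                records[mid] = FrameRecord(t=t, mac_id=mid, active=False,
                                           mode=mode)
                continue
            code, st = csa_step(mac, inputs, mode, params, policy,
                                net.wtable)
            mac.code = code
            mac.code_age = 0
            mac.zeta = st.zeta
            if learn:
                mac.stored_code_count += 1
            records[mid] = FrameRecord(
                t=t, mac_id=mid, active=True, code=[int(c) for c in code],
                G=st.G, zeta=st.zeta, variant=st.variant, mode=mode,
                op_count=st.op_count)
            if learn:
                _collect_correlations(mac, inputs, corr_map)

    if learn:
        plasticity_frame(net, corr_map)

    snap: Snapshot = {}
    for mid in net.order:
        mac = net.macs[mid]
        if mac.active:
            snap[mid] = (mac.cell_activation(),
                         mch_factor(mac.zeta, params))
    return records, snap


def _collect_correlations(mac: Mac, inputs: MacInputs, corr_map: dict) -> None:
    """Queue this mac's afferent (pre, post) pairs for the weight update."""
    post = mac.cell_activation().astype(bool)
    for kind, pre, proj in (("U", inputs.pre_u, mac.u_proj),
                            ("H", inputs.pre_h, mac.h_proj),
                            ("D", inputs.pre_d, mac.d_proj)):
        if pre is None or proj is None:
            continue
        pre_bool = np.asarray(pre) > 0
        if pre_bool.any():
            corr_map[(mac.id, kind)] = (pre_bool, post)


def _check_frames(net: Network, frames: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = []
    for f in frames:
        arr = np.asarray(f).reshape(-1)
        if arr.size != net.input_size:
            raise ValueError(
                f"frame has {arr.size} pixels, model input is {net.input_size}")
        out.append((arr > 0).astype(np.int8))
    return out


def train_sequence(net: Network, frames: Sequence[np.ndarray]) -> Trace:
    """Single-trial learning of one sequence; returns the learning trace.

    Temporal context is reset first, so the sequence is stored as its own
    episode; weights accumulate across calls.
    """
    frames = _check_frames(net, frames)
    net.clear_codes()
    prev: Snapshot = {}
    trace: Trace = []
    for t, pixels in enumerate(frames):
        persisting = tick_persistence(net) if t > 0 else set()
        recs, prev = process_frame(net, pixels, t, LEARNING, True,
                                   persisting, prev)
        trace.append(recs)
    return trace


def train(net: Network, sequences: Sequence[Sequence[np.ndarray]]
          ) -> list[Trace]:
    """Store several sequences in order, one learning trial each."""
    return [train_sequence(net, seq) for seq in sequences]


def recognize_sequence(net: Network, frames: Sequence[np.ndarray],
                       mode: str = SIMPLE) -> Trace:
    """Recall the best-matching stored codes for a test sequence.

    No weights change; codes are re-selected on every frame (no
    persistence hold).  ``mode`` is "simple" (back-off + per-CM hard max,
    deterministic up to seeded tie-breaks) or "probabilistic" (back-off +
    the full softmax round).
    """
    if mode not in MODES or mode == LEARNING:
        raise ValueError("retrieval mode must be 'simple' or 'probabilistic'")
    frames = _check_frames(net, frames)
    net.clear_codes()
    prev: Snapshot = {}
    trace: Trace = []
    for t, pixels in enumerate(frames):
        recs, prev = process_frame(net, pixels, t, mode, False, set(), prev)
        trace.append(recs)
    return trace
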