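"""Hebbian correlation, passive aging and mac-level freezing.

Learning is single-trial and embedding: whenever a mac's code is active on
a frame, every masked synapse from an active presynaptic unit to an active
postsynaptic cell is *correlated* — its age sigma resets to 0 (weight
w_max) and, if the previous correlation happened within the permanence
window T(theta), its permanence theta increments.  All other synapses age
by one frame per frame; weight follows the table's plateau-then-decay
schedule, so unreinforced traces fade while re-visited ones consolidate
until theta_max pins them at w_max forever.

A mac whose afferent weight structure saturates (too large a fraction of
synapses at w_max) has exhausted its storage capacity: all its afferent
projections freeze irreversibly — no further correlation *and* no further
aging — preserving what it has stored.  Efferent projections (which are
other macs' afferents) are unaffected.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .architecture import MacId, Network, Projection
from .weights import WeightTable


def apply_correlation(proj: Projection, pre: np.ndarray, post: np.ndarray,
                      table: WeightTable) -> np.ndarray:
    """Correlate active pre/post pairs of one projection.

    ``pre`` and ``post`` are boolean activation vectors over the
    projection's axes.  Returns the boolean matrix of correlated synapses
    (masked pairs never correlate).  Ages reset to 0; pairs re-correlated
    within their permanence window gain one permanence level.
    """
    if proj.frozen:
        return np.zeros_like(proj.mask)
    corr = (pre.astype(bool)[:, None] & post.astype(bool)[None, :]) & proj.mask
    window = table.window(proj.theta.astype(np.int64))
    repeat = corr & (proj.sigma <= window)
    proj.theta[repeat] = np.minimum(proj.theta[repeat] + 1, table.theta_max)
    proj.sigma[corr] = 0
    return corr


def age_tick(proj: Projection, table: WeightTable,
             exclude: Optional[np.ndarray] = None) -> None:
    """Advance every synapse's age by one frame, capped at sigma_max.

    ``exclude`` marks synapses correlated on this frame (their age stays
    0).  Synapses at maximum permanence are pinned young regardless.
    """
    if proj.frozen:
        return
    aged = np.minimum(proj.sigma.astype(np.int64) + 1, table.sigma_max)
    if exclude is not None:
        aged[exclude] = 0
    proj.sigma[...] = aged.astype(proj.sigma.dtype)
    proj.sigma[proj.theta >= table.theta_max] = 0


def check_freeze(net: Network) -> list[MacId]:
    """Freeze macs whose afferent weights have saturated; return new ids.

    Saturation of any one afferent projection (fraction of synapses at
    w_max meeting the configured threshold) freezes *all* of the mac's
    afferents at once, irreversibly.
    """
    newly = []
    thr = net.config.freeze_threshold
    for mid in net.order:
        mac = net.macs[mid]
        if mac.frozen:
            continue
        if any(p.saturation(net.wtable) >= thr for p in mac.projections()):
            mac.frozen = True
            for p in mac.projections():
                p.frozen = True
            newly.append(mid)
    return newly


def plasticity_frame(net: Network,
                     corr_map: dict[tuple[MacId, str], tuple[np.ndarray, np.ndarray]]
                     ) -> list[MacId]:
    """One learning frame's full weight update across the network.

    ``corr_map`` holds (pre, post) activation pairs for the afferent
    projections of macs that chose or held a code this frame; every other
    projection only ages.  Returns macs newly frozen by this frame.
    """
    table = net.wtable
    for mid in net.order:
        mac = net.macs[mid]
        for proj in mac.projections():
            if proj.frozen:
                continue
            pair = corr_map.get((mid, proj.kind))
            corr = None
            if pair is not None:
                corr = apply_correlation(proj, pair[0], pair[1], table)
            age_tick(proj, table, exclude=corr)
    return check_freeze(net)
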