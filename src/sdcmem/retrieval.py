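"""Retrieval regimes: G-variant back-off and simple (hard-max) recall.

Retrieval reuses the CSA front half: normalized U/H/D inputs are combined
into per-cell support V and per-mac familiarity G, but under a *back-off
protocol* — the most stringent available evidence combination (3-way
G_HUD) is tried first, and only if its familiarity falls below threshold
are progressively more permissive combinations (2-way, then U-only)
evaluated.  Dropping a factor forgives a mismatch in that signal class,
which is what lets recognition re-lock onto a stored sequence after frame
deletions or repetitions (nonlinear time warping).  The candidate list is
fixed by the policy, so back-off leaves the CSA fixed-time.

Two winner rules are offered: *probabilistic* retrieval runs the full
softmax round (steps 9-12), while *simple* retrieval takes the per-CM
hard max of V (seeded tie-break) — deterministic, and forbidden during
learning because it would collapse code diversity.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .architecture import Mac
from .config import BackoffPolicy, CSAParams
from .csa import (MacFrameState, MacInputs, cm_hard_max, familiarity_G,
                  hard_max_winners, local_support, select_variant)
from .engine import recognize_sequence  # noqa: F401  (public driver lives here too)


def evaluate_G_variant(state: MacFrameState, sources: str, q: int, k: int,
                       params: CSAParams) -> tuple[float, np.ndarray]:
    """Familiarity under a restricted evidence-source set.

    ``sources`` is a non-empty subset of "HUD"; omitted factors are
    treated as 1 in the support product.  Returns (G, V per cell).
    """
    if not sources:
        raise ValueError("back-off variant needs at least one evidence source")
    V = local_support(state.U, state.H, state.D, state.t, params, sources)
    v_hat, _ = cm_hard_max(V, q, k)
    return familiarity_G(v_hat), V


def backoff_select(mac: Mac, inputs: MacInputs, state: MacFrameState,
                   params: CSAParams, policy: BackoffPolicy
                   ) -> tuple[str, np.ndarray]:
    """Walk the policy's variant order; return the first acceptable one.

    Variants requiring unavailable sources (t=0 has no H/D; the top level
    has no D) are skipped rather than failed; the terminal U-only variant
    always applies.
    """
    return select_variant(mac, inputs, params, policy, state, retrieval=True)


def simple_retrieve_step(V: np.ndarray, q: int, k: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Simple-mode winner rule: per-CM argmax of V, ties broken by ``rng``."""
    _, argmax = cm_hard_max(V, q, k)
    return hard_max_winners(V.reshape(q, k).max(axis=1), argmax, k, rng)
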