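"""The code selection algorithm (CSA): from U/H/D inputs to a chosen code.

Each frame, every gated mac converts its three afferent signal classes into
one sparse distributed code (one winner per CM) in two competitive rounds:

1. *Deterministic round* (steps 2-8): raw weighted summations are
   normalized to [0,1], multiplicatively combined into per-cell support V,
   hard-maxed within each CM, and averaged into the mac-global familiarity
   G — to first approximation, the similarity of the closest-matching
   stored moment to the current one.
2. *Probabilistic round* (steps 9-12): G sets the expansivity eta of a
   sigmoid V-to-psi map; psi is normalized per CM into win probabilities
   rho, and one winner per CM is drawn (softmax).  As G -> 1 the stored
   code is reinstated almost surely; as G -> 0 winners become uniform,
   minimizing overlap with stored codes.

Every step's cost depends only on the mac's dimensions, never on how many
codes have been stored: storage and best-match retrieval are fixed-time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .architecture import Mac
from .config import BackoffPolicy, CSAParams
from .weights import WeightTable


@dataclass
class MacInputs:
    """Pre-synaptic context for one mac on one frame.

    ``pre_u``/``pre_h``/``pre_d`` are activation vectors over the
    projection's presynaptic axis with the multiple-competing-hypotheses
    factor F of each source mac already multiplied in (pixels carry F=1).
    H and D vectors come from codes active on the previous frame.
    """

    t: int
    pre_u: Optional[np.ndarray] = None
    pre_h: Optional[np.ndarray] = None
    pre_d: Optional[np.ndarray] = None
    pi_u: int = 0            # active features in the U-RF
    pi_u_star: int = 0       # of which non-muddled
    u_reach: int = 0         # cells per U feature (0 -> pixel sources)
    h_feat: int = 0          # active non-muddled H source macs at t-1
    h_reach_sum: int = 0     # total reachable cells across those macs
    d_feat: int = 0
    d_reach_sum: int = 0
    available: frozenset[str] = frozenset({"U"})


@dataclass
class MacFrameState:
    """Everything the CSA computed for one mac on one frame."""

    t: int
    mode: str
    variant: str = ""
    u: Optional[np.ndarray] = None
    h: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    D: Optional[np.ndarray] = None
    V: Optional[np.ndarray] = None
    v_hat: Optional[np.ndarray] = None
    zeta_q: Optional[np.ndarray] = None
    zeta: int = 0
    G: float = 0.0
    eta: float = 1.0
    psi: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None
    op_count: int = 0


# --------------------------------------------------------------- steps 1-3

def gate_mac(code_age: int, delta: int, has_code: bool, pi_u: int,
             bounds: tuple[int, int]) -> bool:
    """Step 1: a mac activates if its code still persists or its U-RF
    carries an in-bounds number of active features."""
    if has_code and code_age < delta:
        return True
    return bounds[0] <= pi_u <= bounds[1]


def raw_summations(mac: Mac, inputs: MacInputs, table: WeightTable,
                   state: MacFrameState) -> None:
    """Step 2: weighted input summations u/h/d per cell.

    Presynaptic activations in ``inputs`` already include the per-source
    F(zeta) factor; H and D presynaptic activity is from the previous
    frame.
    """
    for kind, pre, proj in (("u", inputs.pre_u, mac.u_proj),
                            ("h", inputs.pre_h, mac.h_proj),
                            ("d", inputs.pre_d, mac.d_proj)):
        if pre is None or proj is None:
            continue
        w = proj.weights(table)
        setattr(state, kind, pre @ w)
        state.op_count += 2 * proj.n_pre * proj.n_post


def normalize_inputs(mac: Mac, inputs: MacInputs, params: CSAParams,
                     state: MacFrameState) -> None:
    """Step 3: normalize u/h/d to [0,1] with a hard limit at 1.

    Denominators use the lower feature-count bound so that inputs with
    different numbers of active features compete on an equal footing; at
    level 1 a U feature is one pixel (w_max per feature), above that one
    source mac (Q cells, Q*w_max per feature).  Muddled source macs are
    excluded from the effective feature count (the pi* correction).  For H,
    a cell's own mac contributes Q-1 reachable cells (own-CM pairs carry no
    synapses), so a perfectly familiar moment still normalizes to exactly 1.
    """
    if state.u is not None:
        if inputs.u_reach == 0:  # pixel sources (level 1)
            denom = mac.pi_u[0] * params.w_max
        else:
            eff = min(mac.pi_u[0], inputs.pi_u_star)
            denom = eff * inputs.u_reach * params.w_max
        if denom <= 0:
            if np.any(state.u > 0):
                raise RuntimeError("nonzero U summation with no countable features")
            state.U = np.zeros_like(state.u, dtype=float)
        else:
            state.U = np.clip(state.u / denom, 0.0, 1.0)
        state.op_count += 2 * mac.z
    for kind, feat, reach_sum, lo in (("h", inputs.h_feat, inputs.h_reach_sum,
                                       mac.pi_h_lo),
                                      ("d", inputs.d_feat, inputs.d_reach_sum,
                                       mac.pi_d_lo)):
        raw = getattr(state, kind)
        if raw is None:
            continue
        if feat <= 0:
            setattr(state, kind.upper(), np.zeros_like(raw, dtype=float))
            continue
        reach_avg = reach_sum / feat
        denom = min(lo, feat) * reach_avg * params.w_max
        setattr(state, kind.upper(), np.clip(raw / denom, 0.0, 1.0))
        state.op_count += 2 * mac.z


# --------------------------------------------------------------- steps 4-8

def local_support(U: Optional[np.ndarray], H: Optional[np.ndarray],
                  D: Optional[np.ndarray], t: int, params: CSAParams,
                  sources: str = "HUD") -> np.ndarray:
    """Step 4: per-cell evidential support V as a product of powers.

    Sources absent from ``sources`` (or unavailable, e.g. H/D at t=0) are
    treated as factor 1 — this is also how the retrieval back-off relaxes
    the match criterion.
    """
    parts = []
    if "U" in sources and U is not None:
        parts.append(U ** params.lambda_u_at(t))
    if "H" in sources and H is not None:
        parts.append(H ** params.lambda_h)
    if "D" in sources and D is not None:
        parts.append(D ** params.lambda_d)
    if not parts:
        raise ValueError("local support needs at least one evidence source")
    v = parts[0]
    for p in parts[1:]:
        v = v * p
    return v


def count_mch(V: np.ndarray, q: int, k: int, params: CSAParams,
              active: bool = True) -> tuple[np.ndarray, int]:
    """Step 5: per-CM count of maximally supported cells and the mac-level
    number of competing hypotheses zeta (rounded mean, at least 1 while the
    mac is active: its own code is one hypothesis)."""
    zeta_q = (V.reshape(q, k) > params.v_zeta).sum(axis=1)
    zeta = int(np.floor(zeta_q.mean() + 0.5))
    if active:
        zeta = max(1, zeta)
    return zeta_q, zeta


def mch_factor(zeta: int, params: CSAParams) -> float:
    """Step 6: efferent correction F(zeta): boost small hypothesis counts,
    silence a muddled mac entirely."""
    if not params.mch_enabled:
        return 1.0
    if zeta < 1:
        return 0.0
    if zeta <= params.mch_cutoff:
        return float(zeta) ** params.mch_exponent
    return 0.0


def cm_hard_max(V: np.ndarray, q: int, k: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Step 7: per-CM maximum support and all cells attaining it."""
    v2 = V.reshape(q, k)
    v_hat = v2.max(axis=1)
    argmax = [np.flatnonzero(v2[j] == v_hat[j]) for j in range(q)]
    return v_hat, argmax


def familiarity_G(v_hat: np.ndarray) -> float:
    """Step 8: familiarity of the mac's overall input."""
    return float(v_hat.mean())


# -------------------------------------------------------------- steps 9-12

def sigmoid_range(G: float, k: int, params: CSAParams) -> float:
    """Step 9: expansivity eta of the V-to-psi map; 1 when G <= G-."""
    bracket = max(0.0, (G - params.g_floor) / (1.0 - params.g_floor))
    return 1.0 + bracket ** params.gamma * params.chi * k


def v_to_psi(V: np.ndarray, eta: float, params: CSAParams) -> np.ndarray:
    """Step 10: sigmoid activation function, collapsing to psi=1 at eta=1."""
    z = 1.0 + params.sigma1 * np.exp(-params.sigma2 * (V - params.sigma3))
    return (eta - 1.0) / (z ** params.sigma4) + 1.0


def psi_to_rho(psi: np.ndarray, q: int, k: int) -> np.ndarray:
    """Step 11: per-CM normalization of relative win strengths."""
    p2 = psi.reshape(q, k)
    return (p2 / p2.sum(axis=1, keepdims=True)).reshape(-1)


def draw_winners(rho: np.ndarray, q: int, k: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Step 12: one independent categorical draw per CM (soft max)."""
    r2 = rho.reshape(q, k)
    winners = np.empty(q, dtype=np.int64)
    for j in range(q):
        winners[j] = j * k + rng.choice(k, p=r2[j])
    return winners


def hard_max_winners(v_hat: np.ndarray, argmax: list[np.ndarray], k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Simple-retrieval winner rule: per-CM argmax with seeded tie-break."""
    winners = np.empty(len(argmax), dtype=np.int64)
    for j, cand in enumerate(argmax):
        cell = cand[0] if cand.size == 1 else rng.choice(cand)
        winners[j] = j * k + cell
    return winners


# ------------------------------------------------------------ orchestration

LEARNING = "learning"
PROBABILISTIC = "probabilistic"
SIMPLE = "simple"
MODES = (LEARNING, PROBABILISTIC, SIMPLE)


def select_variant(mac: Mac, inputs: MacInputs, params: CSAParams,
                   policy: BackoffPolicy, state: MacFrameState,
                   retrieval: bool) -> tuple[str, np.ndarray]:
    """Choose the evidence-source combination and return its V vector.

    During learning all available sources are combined.  During retrieval
    the back-off protocol walks the policy's variant order (most stringent
    first) and keeps the first whose familiarity meets its threshold; the
    number of candidate variants is fixed by the policy, so back-off never
    changes the CSA's time complexity.
    """
    avail = inputs.available
    if not retrieval:
        variant = "".join(s for s in "HUD" if s in avail)
        return variant, local_support(state.U, state.H, state.D, inputs.t,
                                      params, variant)
    candidates = [v for v in policy.order if set(v) <= avail]
    if not candidates:
        candidates = ["U"]
    last = None
    for variant in candidates:
        V = local_support(state.U, state.H, state.D, inputs.t, params, variant)
        v_hat = V.reshape(mac.q, mac.k).max(axis=1)
        G = familiarity_G(v_hat)
        state.op_count += mac.z
        last = (variant, V)
        if G >= policy.threshold(variant):
            return variant, V
    return last


def csa_step(mac: Mac, inputs: MacInputs, mode: str, params: CSAParams,
             policy: BackoffPolicy, table: WeightTable,
             rng: Optional[np.random.Generator] = None
             ) -> tuple[np.ndarray, MacFrameState]:
    """Run one full code selection for a gated mac.

    Returns the chosen code (winner cell per CM) and the recorded frame
    state.  ``mode`` is one of learning, probabilistic (retrieval with
    back-off plus the softmax round) or simple (retrieval with back-off,
    winner = per-CM hard max).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else mac.rng
    state = MacFrameState(t=inputs.t, mode=mode)
    raw_summations(mac, inputs, table, state)
    normalize_inputs(mac, inputs, params, state)
    variant, V = select_variant(mac, inputs, params, policy, state,
                                retrieval=(mode != LEARNING))
    state.variant = variant
    state.V = V
    state.zeta_q, state.zeta = count_mch(V, mac.q, mac.k, params)
    v_hat, argmax = cm_hard_max(V, mac.q, mac.k)
    state.v_hat = v_hat
    state.G = familiarity_G(v_hat)
    state.op_count += 4 * mac.z
    if mode == SIMPLE:
        code = hard_max_winners(v_hat, argmax, mac.k, rng)
        state.eta = 1.0
    else:
        state.eta = sigmoid_range(state.G, mac.k, params)
        state.psi = v_to_psi(V, state.eta, params)
        state.rho = psi_to_rho(state.psi, mac.q, mac.k)
        state.op_count += 3 * mac.z
        code = draw_winners(state.rho, mac.q, mac.k, rng)
    return code, state
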