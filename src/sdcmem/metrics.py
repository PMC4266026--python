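"""Recognition accuracy and code-similarity measures over traces.

The elementary measure is the normalized code intersection Gamma: the
fraction of CMs in which two codes of the same mac chose the same winner.
Frame accuracy R_t averages Gamma over the macs that were active in the
learning trace at frame t (a mac inactive at test contributes 0); trace
accuracy R* averages R_t over frames, and R-omega is the final frame's
value.  All are fractions in [0,1]; reports print them x100 to one
decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .architecture import MacId
from .engine import FrameRecord, Trace


def code_similarity(code_a: Sequence[int], code_b: Sequence[int]) -> float:
    """Gamma: per-CM winner agreement between two codes of one mac.

    Codes are winner-per-CM vectors of equal length Q; the intersection
    counts CMs whose winners coincide.
    """
    a = np.asarray(code_a)
    b = np.asarray(code_b)
    if a.shape != b.shape:
        raise ValueError("codes must come from the same mac geometry")
    return float((a == b).mean())


def code_intersection(code_a: Sequence[int], code_b: Sequence[int]) -> int:
    """Raw per-CM intersection count in [0, Q]."""
    return int((np.asarray(code_a) == np.asarray(code_b)).sum())


def frame_accuracy(learn_recs: dict[MacId, FrameRecord],
                   test_recs: dict[MacId, FrameRecord]) -> float:
    """R_t: mean Gamma over macs active in the learning trace at frame t."""
    gammas = []
    for mid, lrec in learn_recs.items():
        if not lrec.active:
            continue
        trec = test_recs.get(mid)
        if trec is None or not trec.active or trec.code is None:
            gammas.append(0.0)
        else:
            gammas.append(code_similarity(lrec.code, trec.code))
    if not gammas:
        return 0.0
    return float(np.mean(gammas))


@dataclass
class AccuracyReport:
    """Per-frame and whole-trace recognition accuracies (fractions)."""

    per_frame: list[float]            # R_t per frame
    r_star: float                     # mean over frames
    r_omega: float                    # final frame
    label: str = ""

    # printed scale: percentages to one decimal, like the benchmark tables
    def per_frame_pct(self) -> list[float]:
        return [round(100 * v, 1) for v in self.per_frame]

    @property
    def r_star_pct(self) -> float:
        return round(100 * self.r_star, 1)

    @property
    def r_omega_pct(self) -> float:
        return round(100 * self.r_omega, 1)

    def to_dict(self) -> dict:
        return {"label": self.label,
                "per_frame_pct": self.per_frame_pct(),
                "r_star_pct": self.r_star_pct,
                "r_omega_pct": self.r_omega_pct}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_csv(self) -> str:
        head = ",".join(["label"] + [f"t{t}" for t in range(len(self.per_frame))]
                        + ["R_star", "R_omega"])
        row = ",".join([self.label or "trace"]
                       + [f"{v:.1f}" for v in self.per_frame_pct()]
                       + [f"{self.r_star_pct:.1f}", f"{self.r_omega_pct:.1f}"])
        return head + "\n" + row + "\n"


def trace_accuracy(learn_trace: Trace, test_trace: Trace,
                   label: str = "") -> AccuracyReport:
    """R* and R-omega for a test trace against its learning trace.

    Frame counts must match (exact-alignment comparison; warp-aware
    alignment is out of scope).
    """
    if len(learn_trace) != len(test_trace):
        raise ValueError("traces must have equal frame counts")
    per_frame = [frame_accuracy(l, t) for l, t in zip(learn_trace, test_trace)]
    if not per_frame:
        return AccuracyReport([], 0.0, 0.0, label)
    return AccuracyReport(per_frame, float(np.mean(per_frame)),
                          per_frame[-1], label)


def intersection_matrix(codes: Sequence[Sequence[int]]) -> np.ndarray:
    """Pairwise per-CM intersection counts among codes of one mac.

    Entry (a, b) is in [0, Q]; the diagonal equals Q.
    """
    arr = np.asarray(codes)
    if arr.ndim != 2:
        raise ValueError("need a list of equal-length codes")
    return (arr[:, None, :] == arr[None, :, :]).sum(axis=2)
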