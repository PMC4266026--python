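"""Effectively binary synapses backed by an age/permanence weight table.

A synapse never stores its weight directly.  It stores an age sigma (frames
since the last pre-post correlation) and a permanence theta (resistance to
passive decay).  The weight in [0, 127] is read from a table indexed by
(theta, sigma): age 0 always maps to w_max = 127; for each permanence level
the weight holds a plateau at 127 for T(theta) frames and then decays
linearly to 0 over another T(theta) frames; at maximum permanence the
weight is pinned at 127 forever.  A blank (never correlated) synapse sits
at (sigma_max, theta=0), i.e. weight 0.
"""

from __future__ import annotations

import numpy as np

from .config import WeightTableParams

W_MAX = 127


class WeightTable:
    """Tabulated (theta, sigma) -> weight map with its decay windows."""

    def __init__(self, params: WeightTableParams | None = None):
        params = params or WeightTableParams()
        self.params = params
        self.theta_max = params.theta_max
        # plateau window per permanence level: T(theta) = base * 2**theta
        self.windows = np.array(
            [params.base_window * (2 ** t) for t in range(self.theta_max + 1)],
            dtype=np.int64,
        )
        self.sigma_max = int(2 * self.windows[self.theta_max])
        table = np.zeros((self.theta_max + 1, self.sigma_max + 1), dtype=np.uint8)
        sig = np.arange(self.sigma_max + 1, dtype=np.float64)
        for theta in range(self.theta_max + 1):
            if theta == self.theta_max:
                table[theta, :] = W_MAX
                continue
            t_w = float(self.windows[theta])
            row = np.where(
                sig <= t_w,
                W_MAX,
                np.clip(np.round(W_MAX * (2.0 * t_w - sig) / t_w), 0, W_MAX),
            )
            table[theta, :] = row.astype(np.uint8)
        self.table = table

    def window(self, theta: np.ndarray | int) -> np.ndarray | int:
        """Re-correlation window T(theta) within which permanence increments."""
        return self.windows[theta]

    def lookup(self, sigma: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Vectorized weight dereference; indices must be in range."""
        if np.any(sigma < 0) or np.any(sigma > self.sigma_max):
            raise ValueError("synapse age out of range")
        if np.any(theta < 0) or np.any(theta > self.theta_max):
            raise ValueError("synapse permanence out of range")
        return self.table[theta, sigma]

    # ------------------------------------------------------------------ io
    def to_csv(self) -> str:
        """Table as CSV, permanence rows by age columns (for inspection)."""
        lines = ["theta\\sigma," + ",".join(str(s) for s in range(self.sigma_max + 1))]
        for theta in range(self.theta_max + 1):
            lines.append(f"{theta}," + ",".join(str(w) for w in self.table[theta]))
        return "\n".join(lines) + "\n"


def weight_lookup(sigma, theta, table: WeightTable):
    """Functional form of :meth:`WeightTable.lookup` (scalars or arrays)."""
    sigma = np.asarray(sigma, dtype=np.int64)
    theta = np.asarray(theta, dtype=np.int64)
    out = table.lookup(sigma, theta)
    return out if out.ndim else int(out)
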