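"""Model, competition and plasticity parameter containers.

A network is described by an input pixel grid plus one entry per internal
level: a grid of macrocolumns ("macs"), each a set of Q winner-take-all
competitive modules (CMs) of K cells.  Code-selection parameters (the
familiarity-modulated softmax competition) live in :class:`CSAParams`;
the retrieval back-off protocol in :class:`BackoffPolicy`; the synaptic
age/permanence decay schedule in :class:`WeightTableParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised for inconsistent architectures (bad tilings, empty models, ...)."""


@dataclass
class CSAParams:
    """Parameters of the per-mac, per-frame code selection competition.

    lambda_u / lambda_h / lambda_d are the exponents applied to the
    normalized bottom-up (U), horizontal (H) and top-down (D) inputs when
    they are multiplied into the per-cell support V.  ``lambda_u_schedule``
    optionally overrides lambda_u per frame index.

    v_zeta is the support threshold above which a cell counts toward a
    maximally active hypothesis; mch_exponent (A) and mch_cutoff (B) shape
    the multiple-competing-hypotheses correction F(z) = z**A for z <= B,
    0 beyond (a "muddled" mac is ignored downstream).

    g_floor (G-), gamma and chi control the expansivity of the sigmoid
    V-to-psi map: eta = 1 + max(0, (G-G-)/(1-G-))**gamma * chi * K, so a
    fully familiar moment (G=1) yields eta = 1 + chi*K.  sigma1..sigma4
    are the sigmoid shape parameters; defaults give a plain logistic with
    slope parameter 10 and midpoint 0.5.
    """

    lambda_u: float = 1.0
    lambda_h: float = 1.0
    lambda_d: float = 1.0
    lambda_u_schedule: Optional[Sequence[float]] = None
    v_zeta: float = 0.95
    mch_exponent: float = 0.7     # A
    mch_cutoff: int = 4           # B
    mch_enabled: bool = True
    g_floor: float = 0.0          # G-
    gamma: float = 2.0
    chi: float = 100.0
    sigma1: float = 1.0
    sigma2: float = 10.0
    sigma3: float = 0.5
    sigma4: float = 1.0
    w_max: int = 127

    def __post_init__(self) -> None:
        if not (0.0 < self.v_zeta <= 1.0):
            raise ConfigurationError("v_zeta must be in (0, 1]")
        if self.mch_exponent >= 1.0:
            raise ConfigurationError("mch_exponent (A) must be < 1")
        if self.mch_cutoff < 1:
            raise ConfigurationError("mch_cutoff (B) must be >= 1")
        if not (0.0 <= self.g_floor < 1.0):
            raise ConfigurationError("g_floor must be in [0, 1)")
        if self.gamma < 1.0:
            raise ConfigurationError("gamma must be >= 1")
        if self.w_max != 127:
            raise ConfigurationError("w_max is fixed at 127")

    def lambda_u_at(self, t: int) -> float:
        sched = self.lambda_u_schedule
        if sched is not None and t < len(sched):
            return float(sched[t])
        return self.lambda_u


#: Evidence-source combinations tried during retrieval, most stringent first.
DEFAULT_BACKOFF_ORDER = ("HUD", "UD", "HU", "HD", "U")


@dataclass
class BackoffPolicy:
    """Ordered match-criterion relaxation used during retrieval.

    The first variant whose familiarity G meets its threshold is used; the
    terminal variant (U-only, threshold 0) always applies.  Variants whose
    evidence sources are unavailable on a frame (t=0 has no H/D; the top
    level has no D) are skipped.
    """

    order: Sequence[str] = DEFAULT_BACKOFF_ORDER
    threshold_three_way: float = 0.9
    threshold_two_way: float = 0.95

    def threshold(self, variant: str) -> float:
        if len(variant) == 3:
            return self.threshold_three_way
        if len(variant) == 2:
            return self.threshold_two_way
        return 0.0

    def __post_init__(self) -> None:
        for v in self.order:
            if not set(v) <= {"U", "H", "D"} or not v:
                raise ConfigurationError(f"unknown back-off variant {v!r}")
        if "U" not in self.order:
            raise ConfigurationError("back-off policy must include the terminal U variant")


@dataclass
class WeightTableParams:
    """Age/permanence decay schedule for the effectively binary synapses."""

    theta_max: int = 2
    base_window: int = 100   # plateau length at permanence 0; doubles per level

    def __post_init__(self) -> None:
        if self.theta_max < 1 or self.base_window < 1:
            raise ConfigurationError("theta_max and base_window must be >= 1")


@dataclass
class LevelConfig:
    """One internal level: a grid of identical macs."""

    grid: tuple[int, int]          # (rows, cols) of macs
    q: int                         # CMs per mac
    k: int                         # cells per CM
    delta: int                     # persistence, frames
    pi_u: tuple[int, int]          # lower/upper bounds on active U features
    pi_h_lo: int = 1               # H normalization bound (no upper gate)
    pi_d_lo: int = 1               # D normalization bound (no upper gate)
    h_radius: int = 1              # Manhattan radius of same-level H sources

    def __post_init__(self) -> None:
        self.grid = tuple(self.grid)  # type: ignore[assignment]
        self.pi_u = tuple(self.pi_u)  # type: ignore[assignment]
        if self.q < 1 or self.k < 2:
            raise ConfigurationError("need Q >= 1 and K >= 2")
        if not (1 <= self.pi_u[0] <= self.pi_u[1]):
            raise ConfigurationError("need 1 <= pi_u_lo <= pi_u_hi")
        if self.delta < 1:
            raise ConfigurationError("persistence delta must be >= 1")

    @property
    def n_macs(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def cells_per_mac(self) -> int:
        return self.q * self.k


@dataclass
class ModelConfig:
    input_grid: tuple[int, int]
    levels: list[LevelConfig]
    csa: CSAParams = field(default_factory=CSAParams)
    backoff: BackoffPolicy = field(default_factory=BackoffPolicy)
    weight_table: WeightTableParams = field(default_factory=WeightTableParams)
    freeze_threshold: float = 0.8
    h_include_own_cm: bool = False

    def __post_init__(self) -> None:
        self.input_grid = tuple(self.input_grid)  # type: ignore[assignment]
        if not self.levels:
            raise ConfigurationError("a network needs at least one internal level")
        if not (0.0 < self.freeze_threshold <= 1.0):
            raise ConfigurationError("freeze_threshold must be in (0, 1]")
        prev = 0
        for lv in self.levels:
            if lv.delta < prev:
                raise ConfigurationError("persistence must be non-decreasing with level")
            prev = lv.delta

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_grid"] = list(self.input_grid)
        for lv in d["levels"]:
            lv["grid"] = list(lv["grid"])
            lv["pi_u"] = list(lv["pi_u"])
        d["backoff"]["order"] = list(self.backoff.order)
        if d["csa"]["lambda_u_schedule"] is not None:
            d["csa"]["lambda_u_schedule"] = list(d["csa"]["lambda_u_schedule"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        levels = [LevelConfig(**lv) for lv in d["levels"]]
        csa = CSAParams(**d.get("csa", {}))
        backoff = BackoffPolicy(**d.get("backoff", {}))
        wt = WeightTableParams(**d.get("weight_table", {}))
        return cls(
            input_grid=tuple(d["input_grid"]),
            levels=levels,
            csa=csa,
            backoff=backoff,
            weight_table=wt,
            freeze_threshold=d.get("freeze_threshold", 0.8),
            h_include_own_cm=d.get("h_include_own_cm", False),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))


def single_mac_config(
    grid: tuple[int, int] = (12, 12),
    q: int = 9,
    k: int = 4,
    pi_u: tuple[int, int] = (9, 12),
    **kwargs,
) -> ModelConfig:
    """One internal level, one mac whose aperture is the whole input grid."""
    level = LevelConfig(grid=(1, 1), q=q, k=k, delta=1, pi_u=pi_u, h_radius=0)
    return ModelConfig(input_grid=grid, levels=[level], **kwargs)
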