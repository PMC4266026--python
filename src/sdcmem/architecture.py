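"""Network construction: levels, macs, competitive modules and projections.

The canonical module is the mac(rocolumn): a grid of Q competitive modules
(CMs, the minicolumn analogue), each holding K cells of which exactly one
is active in any code.  A mac's afferents come in three classes, all
respecting mac borders and shared by every cell of the mac:

* U (bottom-up): all-to-all from every unit in the mac's aperture — pixels
  for level-1 macs, all cells of a tile of subjacent macs above that;
* H (horizontal): from every cell of same-level macs within a Manhattan
  radius (own mac plus N/S/E/W neighbours by default), excluding a cell's
  own CM so that a cell never drives its within-CM competitors;
* D (top-down): all-to-all from every cell of the superjacent parent mac.

Macs tile each level without overlap; U apertures must tile the source
level exactly, which :func:`build_network` validates.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ConfigurationError, ModelConfig
from .weights import W_MAX, WeightTable

MacId = tuple[int, int, int]  # (level, row, col); level 1 is the first internal level


@dataclass
class SourceBlock:
    """A contiguous slice of a projection's presynaptic axis."""

    kind: str                      # "pixels" | "mac"
    offset: int
    size: int
    mac_id: Optional[MacId] = None
    pixel_indices: Optional[np.ndarray] = None  # flat indices into the input grid
    reachable: int = 1             # cells of this source reachable per dest cell

    @property
    def sl(self) -> slice:
        return slice(self.offset, self.offset + self.size)


class Projection:
    """Per-synapse age/permanence arrays backing one afferent class of a mac."""

    def __init__(self, kind: str, dest: MacId, blocks: list[SourceBlock],
                 n_post: int, sigma_max: int, mask: Optional[np.ndarray] = None):
        self.kind = kind
        self.dest = dest
        self.blocks = blocks
        self.n_pre = sum(b.size for b in blocks)
        self.n_post = n_post
        self.sigma = np.full((self.n_pre, n_post), sigma_max, dtype=np.uint16)
        self.theta = np.zeros((self.n_pre, n_post), dtype=np.uint8)
        self.mask = mask if mask is not None else np.ones((self.n_pre, n_post), dtype=bool)
        self.frozen = False

    @property
    def synapse_count(self) -> int:
        return int(self.mask.sum())

    def weights(self, table: WeightTable) -> np.ndarray:
        w = table.lookup(self.sigma.astype(np.int64), self.theta.astype(np.int64))
        return np.where(self.mask, w, 0).astype(np.int64)

    def saturation(self, table: WeightTable, high: int = W_MAX) -> float:
        """Fraction of existing synapses whose weight is at/above ``high``."""
        n = self.synapse_count
        if n == 0:
            return 0.0
        w = self.weights(table)
        return float((w >= high).sum()) / n


class Mac:
    """One macrocolumn with its afferent projections and runtime code state."""

    def __init__(self, mac_id: MacId, q: int, k: int, delta: int,
                 pi_u: tuple[int, int], pi_h_lo: int, pi_d_lo: int):
        self.id = mac_id
        self.q = q
        self.k = k
        self.z = q * k
        self.delta = delta
        self.pi_u = pi_u
        self.pi_h_lo = pi_h_lo
        self.pi_d_lo = pi_d_lo
        self.cm_of_cell = np.repeat(np.arange(q), k)
        self.u_proj: Optional[Projection] = None
        self.h_proj: Optional[Projection] = None
        self.d_proj: Optional[Projection] = None
        # runtime state
        self.code: Optional[np.ndarray] = None   # winner cell index per CM
        self.code_age = 0                        # frames since code activated
        self.zeta = 0                            # MCH count cached at code choice
        self.frozen = False
        self.stored_code_count = 0
        self.rng: Optional[np.random.Generator] = None

    @property
    def active(self) -> bool:
        return self.code is not None

    def cell_activation(self) -> np.ndarray:
        """Binary activation vector over the mac's Z cells."""
        a = np.zeros(self.z, dtype=np.int8)
        if self.code is not None:
            a[self.code] = 1
        return a

    def projections(self) -> list[Projection]:
        return [p for p in (self.u_proj, self.h_proj, self.d_proj) if p is not None]

    def clear(self) -> None:
        self.code = None
        self.code_age = 0
        self.zeta = 0


class Network:
    """A built model: macs per level plus the shared weight table."""

    def __init__(self, config: Optional[ModelConfig], input_size: int,
                 macs: dict[MacId, Mac], wtable: WeightTable):
        self.config = config
        self.input_size = input_size
        self.macs = macs
        self.wtable = wtable
        self.n_levels = max((m[0] for m in macs), default=0)
        # bottom-up evaluation order
        self.order: list[MacId] = sorted(macs)

    @classmethod
    def empty(cls) -> "Network":
        return cls(None, 0, {}, WeightTable())

    def level_macs(self, level: int) -> list[Mac]:
        return [self.macs[m] for m in self.order if m[0] == level]

    # ----------------------------------------------------------- counting
    def count_units(self) -> int:
        """Input pixels plus all internal cells."""
        return self.input_size + sum(m.z for m in self.macs.values())

    def count_weights(self) -> dict[str, int]:
        counts = {"U": 0, "H": 0, "D": 0}
        for mac in self.macs.values():
            for proj in mac.projections():
                counts[proj.kind] += proj.synapse_count
        counts["total"] = counts["U"] + counts["H"] + counts["D"]
        return counts

    # ------------------------------------------------------------- state
    def reset_state(self, seed: int | None = None) -> None:
        """Clear all codes and (re)seed the per-mac random substreams.

        Each mac derives its own generator from (seed, level, row, col) so
        that evaluation order never changes the drawn codes.
        """
        for mac in self.macs.values():
            mac.clear()
            if seed is not None:
                mac.rng = np.random.default_rng(
                    np.random.SeedSequence((int(seed),) + tuple(mac.id))
                )

    def clear_codes(self) -> None:
        """Reset temporal context (between sequences) without reseeding."""
        for mac in self.macs.values():
            mac.clear()

    def snapshot_weights(self) -> dict:
        snap = {}
        for mid, mac in self.macs.items():
            for proj in mac.projections():
                snap[(mid, proj.kind)] = (proj.sigma.copy(), proj.theta.copy(),
                                          proj.frozen)
        snap["__frozen__"] = {mid: m.frozen for mid, m in self.macs.items()}
        snap["__stored__"] = {mid: m.stored_code_count for mid, m in self.macs.items()}
        return snap

    def restore_weights(self, snap: dict) -> None:
        for mid, mac in self.macs.items():
            mac.frozen = snap["__frozen__"][mid]
            mac.stored_code_count = snap["__stored__"][mid]
            for proj in mac.projections():
                sigma, theta, frozen = snap[(mid, proj.kind)]
                proj.sigma[...] = sigma
                proj.theta[...] = theta
                proj.frozen = frozen

    # ---------------------------------------------------------------- io
    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = 1
            f.attrs["config"] = json.dumps(self.config.to_dict())
            for mid, mac in self.macs.items():
                g = f.create_group("mac_%d_%d_%d" % mid)
                g.attrs["frozen"] = mac.frozen
                g.attrs["stored_code_count"] = mac.stored_code_count
                for proj in mac.projections():
                    pg = g.create_group(proj.kind)
                    pg.create_dataset("sigma", data=proj.sigma)
                    pg.create_dataset("theta", data=proj.theta)
                    pg.attrs["frozen"] = proj.frozen

    @classmethod
    def load(cls, path: str) -> "Network":
        import h5py

        with h5py.File(path, "r") as f:
            config = ModelConfig.from_dict(json.loads(f.attrs["config"]))
            net = build_network(config)
            for mid, mac in net.macs.items():
                g = f["mac_%d_%d_%d" % mid]
                mac.frozen = bool(g.attrs["frozen"])
                mac.stored_code_count = int(g.attrs["stored_code_count"])
                for proj in mac.projections():
                    pg = g[proj.kind]
                    proj.sigma[...] = pg["sigma"][...]
                    proj.theta[...] = pg["theta"][...]
                    proj.frozen = bool(pg.attrs["frozen"])
        return net


# ---------------------------------------------------------------- builders

def _tile_factors(src: tuple[int, int], dst: tuple[int, int]) -> tuple[int, int]:
    fr, fc = src[0] // dst[0], src[1] // dst[1]
    if dst[0] * fr != src[0] or dst[1] * fc != src[1]:
        raise ConfigurationError(
            f"aperture tiling {dst} does not divide source grid {src} exactly"
        )
    return fr, fc


def build_network(config: ModelConfig) -> Network:
    """Instantiate all macs, CMs and U/H/D projections for ``config``.

    Deterministic: two builds from the same config are structurally
    identical.  All synapses start blank (age sigma_max, permanence 0,
    weight 0).
    """
    wtable = WeightTable(config.weight_table)
    sigma_max = wtable.sigma_max
    in_rows, in_cols = config.input_grid
    macs: dict[MacId, Mac] = {}

    grids = [lv.grid for lv in config.levels]
    for li, lv in enumerate(config.levels, start=1):
        for r in range(lv.grid[0]):
            for c in range(lv.grid[1]):
                macs[(li, r, c)] = Mac((li, r, c), lv.q, lv.k, lv.delta,
                                       lv.pi_u, lv.pi_h_lo, lv.pi_d_lo)

    for li, lv in enumerate(config.levels, start=1):
        below = config.levels[li - 2] if li >= 2 else None
        above = config.levels[li] if li < len(config.levels) else None
        if li == 1:
            fr, fc = _tile_factors((in_rows, in_cols), lv.grid)
        else:
            fr, fc = _tile_factors(below.grid, lv.grid)
        if above is not None:
            pfr, pfc = _tile_factors(lv.grid, above.grid)

        for r in range(lv.grid[0]):
            for c in range(lv.grid[1]):
                mac = macs[(li, r, c)]
                # ---------------------------------------------------- U
                if li == 1:
                    rows = np.arange(r * fr, (r + 1) * fr)
                    cols = np.arange(c * fc, (c + 1) * fc)
                    flat = (rows[:, None] * in_cols + cols[None, :]).ravel()
                    blocks = [SourceBlock("pixels", 0, flat.size,
                                          pixel_indices=flat)]
                else:
                    blocks = []
                    off = 0
                    for sr in range(r * fr, (r + 1) * fr):
                        for sc in range(c * fc, (c + 1) * fc):
                            src = macs[(li - 1, sr, sc)]
                            blocks.append(SourceBlock("mac", off, src.z,
                                                      mac_id=src.id,
                                                      reachable=src.q))
                            off += src.z
                mac.u_proj = Projection("U", mac.id, blocks, mac.z, sigma_max)

                # ---------------------------------------------------- H
                blocks = []
                off = 0
                for sr in range(lv.grid[0]):
                    for sc in range(lv.grid[1]):
                        if abs(sr - r) + abs(sc - c) > lv.h_radius:
                            continue
                        src = macs[(li, sr, sc)]
                        own = src.id == mac.id and not config.h_include_own_cm
                        blocks.append(SourceBlock(
                            "mac", off, src.z, mac_id=src.id,
                            reachable=src.q - 1 if own else src.q))
                        off += src.z
                n_pre = off
                mask = np.ones((n_pre, mac.z), dtype=bool)
                if not config.h_include_own_cm:
                    for b in blocks:
                        if b.mac_id == mac.id:
                            same_cm = (mac.cm_of_cell[:, None]
                                       == mac.cm_of_cell[None, :])
                            mask[b.sl, :] = ~same_cm
                mac.h_proj = Projection("H", mac.id, blocks, mac.z, sigma_max,
                                        mask=mask)

                # ---------------------------------------------------- D
                if above is not None:
                    parent = macs[(li + 1, r // pfr, c // pfc)]
                    blocks = [SourceBlock("mac", 0, parent.z,
                                          mac_id=parent.id,
                                          reachable=parent.q)]
                    mac.d_proj = Projection("D", mac.id, blocks, mac.z,
                                            sigma_max)

    net = Network(config, in_rows * in_cols, macs, wtable)
    net.reset_state(seed=0)
    return net


def count_units(network: Network) -> int:
    return network.count_units()


def count_weights(network: Network) -> dict[str, int]:
    return network.count_weights()


def tick_persistence(network: Network) -> set[MacId]:
    """Advance code ages; return ids of macs whose code persists this frame.

    A code chosen on frame t has age 0; it persists on a later frame while
    its incremented age stays below the level's persistence delta.  Expired
    codes are left in place for the caller to replace (the mac becomes
    eligible for new code selection).
    """
    persisting: set[MacId] = set()
    for mid in network.order:
        mac = network.macs[mid]
        if mac.code is None:
            continue
        mac.code_age += 1
        if mac.code_age < mac.delta:
            persisting.add(mid)
    return persisting
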