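"""Synthetic input generators: the model's entire test-data harness.

Inputs are sequences of sparse binary 2-D frames (pre-skeletonized edge
images in the intended application; structured random patterns here).
Generators cover the four study designs: random frame sequences with a
controlled active-pixel count, pixel-relocation noise, frame deletion /
repetition time warps, an overlap ladder (first frames sharing a
decreasing fraction of pixels, second frame common) and multi-aperture
frames that gate a chosen subset of level-1 macs.

All generators are seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameSequence:
    """An ordered list of binary frames, stored as active-pixel index sets."""

    grid: tuple[int, int]
    frames: list[np.ndarray]          # sorted flat indices per frame
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = tuple(self.grid)  # type: ignore[assignment]
        size = self.grid[0] * self.grid[1]
        clean = []
        for f in self.frames:
            arr = np.unique(np.asarray(f, dtype=np.int64))
            if arr.size and (arr[0] < 0 or arr[-1] >= size):
                raise ValueError("active-pixel index outside grid")
            clean.append(arr)
        self.frames = clean

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def size(self) -> int:
        return self.grid[0] * self.grid[1]

    def to_dense(self) -> list[np.ndarray]:
        """Frames as flat 0/1 vectors (the engine's input format)."""
        out = []
        for f in self.frames:
            v = np.zeros(self.size, dtype=np.int8)
            v[f] = 1
            out.append(v)
        return out

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {"grid": list(self.grid),
                "frames": [[int(i) for i in f] for f in self.frames],
                "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSequence":
        return cls(grid=tuple(d["grid"]),
                   frames=[np.asarray(f, dtype=np.int64) for f in d["frames"]],
                   label=d.get("label", ""))


def save_sequences(seqs: list[FrameSequence], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in seqs], fh, indent=1)


def load_sequences(path: str) -> list[FrameSequence]:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [FrameSequence.from_dict(d) for d in data]


# ------------------------------------------------------------- generators

def gen_random_sequences(n_seq: int, n_frames: int, grid: tuple[int, int],
                         active_range: tuple[int, int], seed: int
                         ) -> list[FrameSequence]:
    """Random sequences: per frame, an active-pixel count drawn uniformly
    from ``active_range`` and positions drawn uniformly without
    replacement."""
    size = grid[0] * grid[1]
    lo, hi = active_range
    if not (0 <= lo <= hi <= size):
        raise ValueError("active_range must satisfy 0 <= lo <= hi <= grid size")
    rng = np.random.default_rng(seed)
    seqs = []
    for s in range(n_seq):
        frames = []
        for _ in range(n_frames):
            n = int(rng.integers(lo, hi + 1))
            frames.append(np.sort(rng.choice(size, size=n, replace=False)))
        seqs.append(FrameSequence(grid=grid, frames=frames, label=f"seq{s}"))
    return seqs


def perturb_sequence(seq: FrameSequence, n_changed: int, seed: int
                     ) -> FrameSequence:
    """Relocation noise: per frame, ``n_changed`` active pixels move to
    previously inactive positions.

    The active count is preserved and the symmetric difference with the
    original frame is exactly 2 * n_changed (one "changed" pixel yields
    two pixel-level differences).
    """
    rng = np.random.default_rng(seed)
    size = seq.size
    frames = []
    for f in seq.frames:
        inactive = np.setdiff1d(np.arange(size), f, assume_unique=False)
        if n_changed > f.size or n_changed > inactive.size:
            raise ValueError("frame too small for the requested perturbation")
        off = rng.choice(f, size=n_changed, replace=False)
        on = rng.choice(inactive, size=n_changed, replace=False)
        frames.append(np.sort(np.concatenate(
            [np.setdiff1d(f, off, assume_unique=False), on])))
    return FrameSequence(grid=seq.grid, frames=frames,
                         label=f"{seq.label}+noise{n_changed}")


def warp_sequence(seq: FrameSequence, schedule: dict[int, str]
                  ) -> FrameSequence:
    """Time-warp a sequence: delete or repeat frames by original position.

    ``schedule`` maps frame index to "delete" (speed-up) or "repeat"
    (slow-down: the frame appears twice).  An empty schedule is identity.
    """
    frames = []
    for i, f in enumerate(seq.frames):
        op = schedule.get(i)
        if op is None:
            frames.append(f)
        elif op == "delete":
            continue
        elif op == "repeat":
            frames.extend([f, f])
        else:
            raise ValueError(f"unknown warp op {op!r} at position {i}")
    return FrameSequence(grid=seq.grid, frames=frames,
                         label=f"{seq.label}+warp")


def gen_overlap_ladder(grid: tuple[int, int], n_levels: int, seed: int,
                       n_active: int = 12, shared_second_frame: bool = True
                       ) -> tuple[list[FrameSequence], list[float]]:
    """Overlap ladder: 2-frame sequences whose first frames share a
    strictly decreasing fraction of pixels with the first sequence's.

    Sequence 0's first frame is the reference; sequence i's first frame
    keeps a fraction ~ (1 - i/(n-1)) of its pixels (100% down to 0%) and
    replaces the rest with pixels disjoint from the reference.  All
    sequences share the same second frame when ``shared_second_frame``.
    Returns (sequences, realized overlap fractions).
    """
    if n_levels < 2:
        raise ValueError("an overlap ladder needs at least 2 levels")
    size = grid[0] * grid[1]
    rng = np.random.default_rng(seed)
    ref = np.sort(rng.choice(size, size=n_active, replace=False))
    others = np.setdiff1d(np.arange(size), ref)
    second = np.sort(rng.choice(size, size=n_active, replace=False))
    seqs, overlaps = [], []
    for i in range(n_levels):
        shared = int(round(n_active * (1 - i / (n_levels - 1))))
        keep = rng.choice(ref, size=shared, replace=False)
        fill = rng.choice(others, size=n_active - shared, replace=False)
        first = np.sort(np.concatenate([keep, fill]))
        f2 = second if shared_second_frame else np.sort(
            rng.choice(size, size=n_active, replace=False))
        seqs.append(FrameSequence(grid=grid, frames=[first, f2],
                                  label=f"ladder{i}"))
        overlaps.append(np.intersect1d(first, ref).size / n_active)
    return seqs, overlaps


def gen_hierarchical_frames(grid: tuple[int, int], aperture: tuple[int, int],
                            per_aperture_range: tuple[int, int],
                            n_frames: int, eligible: int, seed: int
                            ) -> FrameSequence:
    """Frames for a tiled multi-mac level-1 layer.

    Each frame makes exactly ``eligible`` apertures gate-eligible (active
    count drawn from ``per_aperture_range``) and the rest ineligible
    (fewer than the range's lower bound).
    """
    gr, gc = grid
    ar, ac = aperture
    if gr % ar or gc % ac:
        raise ValueError("aperture does not tile the grid exactly")
    tiles_r, tiles_c = gr // ar, gc // ac
    n_tiles = tiles_r * tiles_c
    lo, hi = per_aperture_range
    if not (0 < lo <= hi <= ar * ac):
        raise ValueError("per-aperture range outside aperture capacity")
    if not (0 <= eligible <= n_tiles):
        raise ValueError("eligible aperture count outside tiling")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        chosen = rng.choice(n_tiles, size=eligible, replace=False)
        active = []
        for tile in range(n_tiles):
            tr, tc = divmod(tile, tiles_c)
            if tile in chosen:
                n = int(rng.integers(lo, hi + 1))
            else:
                n = int(rng.integers(0, lo))
            local = rng.choice(ar * ac, size=n, replace=False)
            rows = tr * ar + local // ac
            cols = tc * ac + local % ac
            active.append(rows * gc + cols)
        frames.append(np.sort(np.concatenate(active)) if active else
                      np.array([], dtype=np.int64))
    return FrameSequence(grid=grid, frames=frames, label="hier")
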