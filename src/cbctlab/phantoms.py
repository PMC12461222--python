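"""Synthetic phantoms and motion trajectories.

The generator stands in for patient CBCT scans: a head ellipse of soft
tissue with a bone rim, a lower-jaw arch carrying tooth disks, and
optional high-attenuation metal inserts (the regions D1, D2 used in the
two-metal interaction experiment).  Motion is modelled as per-view rigid
y-translation confined to a contiguous window of views, with piecewise
constant displacements bounded by a configured maximum.

All generators are pure functions of their arguments plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from .materials import MATERIAL_PRESETS, Material

__all__ = [
    "Phantom",
    "MotionTrajectory",
    "make_toy_phantom",
    "make_dental_phantom",
    "insert_metal",
    "make_motion_trajectory",
    "AIR",
    "SOFT",
    "BONE",
    "TOOTH",
    "METAL",
]

AIR, SOFT, BONE, TOOTH, METAL = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class Phantom:
    """Material-label grid with physical pixel size.

    ``labels`` is an integer 2D (row, col) or 3D (row, col, slice) grid;
    ``material_map`` assigns a :class:`~cbctlab.materials.Material` to
    every label that occurs.
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    material_map: Dict[int, Material] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        missing = set(np.unique(lab).tolist()) - set(self.material_map)
        if missing:
            raise ValueError(f"labels without material: {sorted(missing)}")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class MotionTrajectory:
    """Per-view rigid y-displacements, zero outside ``active_window``."""

    displacements: np.ndarray  # (n_views,) in length units
    active_window: tuple  # [start, stop) view indices
    max_disp: float

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        lo, hi = self.active_window
        outside = np.ones(d.size, dtype=bool)
        outside[lo:hi] = False
        if np.any(d[outside] != 0):
            raise ValueError("displacement outside the active window")
        if np.any(np.abs(d) > self.max_disp + 1e-12):
            raise ValueError("displacement exceeds max_disp")
        object.__setattr__(self, "displacements", d)

    @property
    def n_views(self) -> int:
        return self.displacements.size


_TOY_MAP = {0: MATERIAL_PRESETS["air"], 1: MATERIAL_PRESETS["toy_metal"]}

_DENTAL_MAP = {
    AIR: MATERIAL_PRESETS["air"],
    SOFT: MATERIAL_PRESETS["soft_tissue"],
    BONE: MATERIAL_PRESETS["bone"],
    TOOTH: MATERIAL_PRESETS["tooth"],
    METAL: MATERIAL_PRESETS["metal"],
}


def make_toy_phantom() -> Phantom:
    """The 3x3 worked-example phantom: metal at (row 2, col 1) and
    (row 2, col 3), air elsewhere, unit pixels."""
    labels = np.zeros((3, 3), dtype=np.int64)
    labels[1, 0] = 1
    labels[1, 2] = 1
    return Phantom(labels, 1.0, dict(_TOY_MAP))


def make_dental_phantom(size: int = 64, n_teeth: int = 8, seed: int = 0) -> Phantom:
    """Random head/jaw phantom: soft-tissue head ellipse, bone skull rim,
    lower-jaw bone arch with ``n_teeth`` tooth disks.

    Reproducible for a fixed seed; contains no metal (use
    :func:`insert_metal` for that).
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    n = size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy, cx = (n - 1) / 2.0, (n - 1) / 2.0
    a = 0.44 * n * (1 + 0.04 * rng.uniform(-1, 1))  # semi-axis along columns
    b = 0.40 * n * (1 + 0.04 * rng.uniform(-1, 1))
    labels = np.zeros((n, n), dtype=np.int64)
    head = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    rim = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 >= 0.82
    labels[head] = SOFT
    labels[head & rim] = BONE

    # lower-jaw arch: a band of bone along a semi-ellipse opening upward,
    # carrying evenly spaced tooth disks
    arch_a, arch_b = 0.26 * n, 0.24 * n
    jaw_cy = cy + 0.08 * n
    arch = np.abs(np.sqrt(((xx - cx) / arch_a) ** 2 + ((yy - jaw_cy) / arch_b) ** 2) - 1.0) < 0.10
    labels[arch & (yy > jaw_cy) & head] = BONE

    t_angles = np.linspace(0.15 * np.pi, 0.85 * np.pi, n_teeth)
    r_tooth = max(1.6, 0.028 * n)
    arch_len = np.pi * max(arch_a, arch_b)
    if n_teeth > arch_len / (2 * r_tooth):
        raise ValueError("n_teeth exceeds arch capacity")
    for ang in t_angles:
        tx = cx + arch_a * np.cos(ang)
        ty = jaw_cy + arch_b * np.sin(ang)
        disk = (xx - tx) ** 2 + (yy - ty) ** 2 <= r_tooth**2
        labels[disk & head] = TOOTH
    return Phantom(labels, 1.0, dict(_DENTAL_MAP))


def insert_metal(phantom: Phantom, center, radius: float, label: int = METAL) -> Phantom:
    """Return a new phantom with a disk (2D) or sphere (3D) relabelled to
    ``label``; the original is unchanged."""
    lab = phantom.labels
    c = np.asarray(center, dtype=float)
    if c.size != lab.ndim:
        raise ValueError("center dimensionality mismatch")
    if np.any(c - radius < -0.5) or np.any(c + radius > np.asarray(lab.shape) - 0.5):
        raise ValueError("disk out of bounds")
    new = lab.copy()
    if radius > 0:  # a disk of zero radius is empty
        grids = np.ogrid[tuple(slice(0, s) for s in lab.shape)]
        dist2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        new[dist2 <= radius**2] = label
    mmap = dict(phantom.material_map)
    if label not in mmap:
        mmap[label] = _DENTAL_MAP[label]
    return Phantom(new, phantom.pixel_size, mmap)


def make_motion_trajectory(
    n_views: int,
    window=(80, 140),
    max_disp: float = 5.0,
    n_events: int = 3,
    seed: int = 0,
) -> MotionTrajectory:
    """Piecewise-constant random y-displacements inside ``window``.

    ``n_events`` constant segments partition the window; each segment's
    displacement is uniform in [-max_disp, max_disp].  Views outside the
    window are exactly zero.
    """
    lo, hi = window
    if not (0 <= lo <= hi <= n_views):
        raise ValueError("window must lie within [0, n_views]")
    rng = np.random.default_rng(seed)
    d = np.zeros(n_views, dtype=float)
    if hi > lo and max_disp > 0 and n_events > 0:
        cuts = np.sort(rng.choice(np.arange(lo + 1, hi), size=min(n_events - 1, hi - lo - 1), replace=False)) if n_events > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[lo], cuts, [hi]]).astype(int)
        for k in range(len(bounds) - 1):
            d[bounds[k] : bounds[k + 1]] = rng.uniform(-max_disp, max_disp)
    return MotionTrajectory(d, (lo, hi), max_disp)


def erase_metal(phantom: Phantom, metal_label: int = METAL, fill: int = SOFT) -> Phantom:
    """Relabel all metal pixels back to ``fill`` (inverse of insertion
    over soft tissue)."""
    new = phantom.labels.copy()
    new[new == metal_label] = fill
    return replace(phantom, labels=new)
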