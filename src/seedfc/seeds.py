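"""Seed time-series extraction and decontamination.

One representative series per seed per subject-session: the arithmetic mean
over the seed-mask voxels, optionally cleaned by regressing out signals
from small spheres placed in adjacent structures (to remove partial-volume
contamination from neighbouring nuclei).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import RoiMask, TimeSeriesImage

__all__ = [
    "SeedSeries",
    "mean_roi_timeseries",
    "extract_seed",
    "clean_seed_series",
    "sphere_mask",
    "combine_masks",
]


@dataclass
class SeedSeries:
    """A seed's representative time series with extraction provenance."""

    name: str
    series: np.ndarray
    n_voxels: int = 1
    nuisance_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float).ravel()
        if not np.isfinite(self.series).all():
            raise ValueError(f"seed {self.name!r} series contains non-finite values")
        if self.n_voxels < 1:
            raise ValueError("seed mask must contain at least one voxel")


def mean_roi_timeseries(img: TimeSeriesImage | np.ndarray, mask: RoiMask | np.ndarray
                        ) -> np.ndarray:
    """Mean over mask voxels at each timepoint; (T,) array."""
    data = img.data if isinstance(img, TimeSeriesImage) else np.asarray(img)
    m = (mask.data if isinstance(mask, RoiMask) else np.asarray(mask)).astype(bool)
    if data.shape[:3] != m.shape:
        raise ValueError(f"mask grid {m.shape} does not match image grid {data.shape[:3]}")
    if not m.any():
        raise ValueError("empty ROI mask")
    return data[m].mean(axis=0).astype(float)


def extract_seed(img: TimeSeriesImage, mask: RoiMask,
                 contamination_series: list[np.ndarray] | None = None,
                 contamination_labels: list[str] | None = None) -> SeedSeries:
    """Mask-average series, then contamination cleanup if spheres are given."""
    seed = SeedSeries(name=mask.name, series=mean_roi_timeseries(img, mask),
                      n_voxels=mask.n_voxels)
    if contamination_series:
        seed = clean_seed_series(seed, contamination_series, contamination_labels)
    return seed


def clean_seed_series(seed: SeedSeries, spheres: list[np.ndarray],
                      labels: list[str] | None = None) -> SeedSeries:
    """Residual of the seed series after regression on sphere series + intercept.

    With no spheres the series is returned demeaned.  Idempotent: a second
    application with the same spheres is a no-op to numerical tolerance.
    """
    y = seed.series
    T = y.size
    if not spheres:
        return replace(seed, series=y - y.mean())
    S = np.column_stack([np.asarray(s, dtype=float).ravel() for s in spheres])
    if S.shape[0] != T:
        raise ValueError(f"sphere series length {S.shape[0]} != seed length {T}")
    labels = labels or [f"sphere_{i}" for i in range(S.shape[1])]
    design = np.column_stack([np.ones(T), S])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear sphere set: {labels}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return replace(seed, series=y - design @ beta,
                   nuisance_labels=tuple(seed.nuisance_labels) + tuple(labels))


def sphere_mask(name: str, center_voxel: tuple[int, int, int], radius_mm: float,
                grid_shape: tuple[int, int, int], voxel_size_mm: float = 2.0) -> RoiMask:
    """Closed-ball mask: voxels whose center lies within ``radius_mm`` of the
    center voxel's center (distances in mm via the voxel size)."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    grids = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    d2 = sum(((g - c) * voxel_size_mm) ** 2 for g, c in zip(grids, center_voxel))
    return RoiMask(name, (d2 <= radius_mm**2).astype(np.uint8))


def combine_masks(masks: list[RoiMask], name: str | None = None,
                  method: str = "majority") -> RoiMask:
    """Combine binary masks voxelwise: 'majority' (mean >= 0.5, e.g. to pool
    per-session segmentations), 'intersect', or 'union'."""
    if not masks:
        raise ValueError("no masks to combine")
    stack = np.stack([m.data for m in masks]).astype(float)
    if method == "majority":
        out = stack.mean(axis=0) >= 0.5
    elif method == "intersect":
        out = stack.min(axis=0) > 0
    elif method == "union":
        out = stack.max(axis=0) > 0
    else:
        raise ValueError(f"unknown combine method {method!r}")
    return RoiMask(name or f"{method}_{'_'.join(m.name for m in masks)}",
                   out.astype(np.uint8))
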