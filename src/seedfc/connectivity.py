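"""Seed-to-whole-brain static FC and dynamic FC variability maps.

Static FC (sFC): Fisher-z of the full-length Pearson correlation between the
seed series and every brain voxel.  Dynamic FC variability (dFCv): a tapered
sliding window (default 84 TRs = 67 s at TR 0.8 s, Hamming taper, step 1 TR)
is slid over the series; within each window a taper-weighted correlation is
computed and Fisher-z transformed, and the sample standard deviation (N-1)
of the windowed z values is the voxel's dFCv.

The taper enters as observation weights inside the correlation (weighted
means and covariances), which keeps r in [-1, 1] exactly and reduces to the
plain Pearson correlation for equal weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .denoise import BandSpec
from .seeds import SeedSeries
from .synthetic import RoiMask, TimeSeriesImage

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7  # Fisher-z clipping bound for |r| -> 1

__all__ = [
    "WindowSpec",
    "ConnectivityMap",
    "WindowSensitivityResult",
    "hamming_weights",
    "weighted_corr",
    "fisher_z",
    "n_windows",
    "trs_for_seconds",
    "check_min_window",
    "static_fc_map",
    "dfcv_map",
    "window_sensitivity",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length W in TRs, step in TRs, taper."""

    window_trs: int = 84
    step_trs: int = 1
    taper: str = "hamming"

    def __post_init__(self) -> None:
        if self.window_trs < 2:
            raise ValueError("window_trs must be >= 2")
        if self.step_trs < 1:
            raise ValueError("step_trs must be >= 1")
        if self.taper not in ("hamming", "rectangular"):
            raise ValueError(f"taper must be 'hamming' or 'rectangular', got {self.taper!r}")

    def weights(self) -> np.ndarray:
        if self.taper == "hamming":
            return hamming_weights(self.window_trs)
        return np.ones(self.window_trs)

    def seconds(self, tr_seconds: float) -> float:
        return self.window_trs * tr_seconds


@dataclass
class ConnectivityMap:
    """3-D map of Fisher-z sFC or dFCv values for one seed/subject/session."""

    data: np.ndarray
    kind: str  # 'sfc_z' | 'dfcv'
    seed_name: str = ""
    subject_id: str = ""
    session: str = ""
    window: WindowSpec | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kind not in ("sfc_z", "dfcv"):
            raise ValueError(f"kind must be 'sfc_z' or 'dfcv', got {self.kind!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("connectivity map contains non-finite values")
        if self.kind == "dfcv" and (self.data < 0).any():
            raise ValueError("dFCv values must be >= 0")


@dataclass
class WindowSensitivityResult:
    maps: list[ConnectivityMap]
    pairwise_correlations: pd.DataFrame


def hamming_weights(W: int) -> np.ndarray:
    """Hamming taper w_k = 0.54 - 0.46 cos(2*pi*k/(W-1)), k = 0..W-1."""
    if W < 2:
        raise ValueError("Hamming window needs W >= 2")
    k = np.arange(W)
    w = 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (W - 1))
    return 0.5 * (w + w[::-1])  # enforce exact symmetry in floating point


def _weighted_corr_vec(x: np.ndarray, Y: np.ndarray, w: np.ndarray
                       ) -> tuple[np.ndarray, int]:
    """Weighted correlation of x (W,) against each column of Y (W, V).

    Returns (r values, count of zero-variance columns mapped to r = 0).
    """
    p = w / w.sum()
    xc = x - p @ x
    Yc = Y - p @ Y
    vx = p @ xc**2
    if vx <= 0:
        raise ValueError("zero weighted variance in seed window")
    vy = p @ Yc**2
    cov = (p * xc) @ Yc
    bad = vy <= 0
    denom = np.sqrt(vx * np.where(bad, 1.0, vy))
    r = np.where(bad, 0.0, cov / denom)
    return np.clip(r, -1.0, 1.0), int(bad.sum())


def weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Taper-weighted Pearson correlation of two equal-length series.

    With probability weights p = w/sum(w):
    r = sum p (x-mx)(y-my) / sqrt(sum p (x-mx)^2 * sum p (y-my)^2).
    Equal weights reduce exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    r, bad = _weighted_corr_vec(x, y[:, None], w)
    if bad:
        raise ValueError("zero weighted variance in y")
    return float(r[0])


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z = atanh(r), with |r| clipped to 1 - 1e-7 to keep z finite."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) else out


def n_windows(T: int, spec: WindowSpec) -> int:
    """Number of sliding windows: floor((T - W)/step) + 1."""
    if T < spec.window_trs:
        raise ValueError(
            f"series length {T} shorter than window of {spec.window_trs} TRs; "
            "the window cannot exceed the series"
        )
    return (T - spec.window_trs) // spec.step_trs + 1


def trs_for_seconds(seconds: float, tr_seconds: float) -> int:
    """Window length in TRs nearest to a duration in seconds, half rounded up
    (100 s at TR 0.8 s -> 125 TRs; 50 s -> 63 TRs)."""
    if seconds <= 0 or tr_seconds <= 0:
        raise ValueError("durations must be positive")
    return int(np.floor(seconds / tr_seconds + 0.5))


def check_min_window(spec: WindowSpec, tr_seconds: float, band: BandSpec) -> None:
    """Minimum-window rule: the window must span at least one period of the
    slowest retained frequency (W * TR >= 1/f_low)."""
    w_sec = spec.seconds(tr_seconds)
    min_sec = 1.0 / band.f_low
    if w_sec < min_sec:
        raise ValueError(
            f"window of {w_sec:.1f} s is shorter than 1/f_low = {min_sec:.1f} s; "
            "sliding windows must be no shorter than one period of the slowest "
            "retained frequency"
        )


def _masked_series(img: TimeSeriesImage, brain_mask: RoiMask) -> tuple[np.ndarray, np.ndarray]:
    m = brain_mask.data.astype(bool)
    if img.grid_shape != m.shape:
        raise ValueError("brain mask grid does not match image grid")
    if not m.any():
        raise ValueError("empty brain mask")
    return img.data[m].T.astype(float), m  # (T, V), mask


def static_fc_map(seed: SeedSeries, img: TimeSeriesImage, brain_mask: RoiMask
                  ) -> ConnectivityMap:
    """Fisher-z map of full-length Pearson correlation seed vs every brain voxel."""
    Y, m = _masked_series(img, brain_mask)
    x = seed.series
    if x.size != Y.shape[0]:
        raise ValueError("seed series length does not match image")
    if x.std() == 0:
        raise ValueError("zero-variance seed series")
    r, bad = _weighted_corr_vec(x, Y, np.ones(x.size))
    if bad:
        logger.warning("static FC: %d zero-variance voxels set to r=0", bad)
    out = np.zeros(m.shape)
    out[m] = fisher_z(r)
    return ConnectivityMap(out, "sfc_z", seed_name=seed.name,
                           subject_id=img.subject_id, session=img.session)


def dfcv_map(seed: SeedSeries, img: TimeSeriesImage, brain_mask: RoiMask,
             spec: WindowSpec | None = None) -> ConnectivityMap:
    """Sliding-window dFCv map: SD (N-1) across windows of windowed Fisher-z."""
    spec = spec or WindowSpec()
    Y, m = _masked_series(img, brain_mask)
    x = seed.series
    T = x.size
    nw = n_windows(T, spec)
    if nw < 2:
        raise ValueError("dFCv needs at least 2 windows; lengthen the series "
                         "or shorten the window")
    w = spec.weights()
    W = spec.window_trs
    zs = np.empty((nw, Y.shape[1]))
    n_bad = 0
    for i in range(nw):
        t0 = i * spec.step_trs
        r, bad = _weighted_corr_vec(x[t0:t0 + W], Y[t0:t0 + W], w)
        n_bad += bad
        zs[i] = fisher_z(r)
    if n_bad:
        logger.warning("dFCv: %d zero-variance window-voxels set to r=0", n_bad)
    out = np.zeros(m.shape)
    out[m] = zs.std(axis=0, ddof=1)
    return ConnectivityMap(out, "dfcv", seed_name=seed.name,
                           subject_id=img.subject_id, session=img.session,
                           window=spec)


def window_sensitivity(seed: SeedSeries, img: TimeSeriesImage, brain_mask: RoiMask,
                       specs: list[WindowSpec]) -> WindowSensitivityResult:
    """dFCv maps for several window lengths plus their pairwise voxel-wise
    correlations over the brain mask (window-length robustness check)."""
    maps = [dfcv_map(seed, img, brain_mask, s) for s in specs]
    m = brain_mask.data.astype(bool)
    names = [f"W={s.window_trs}" for s in specs]
    vals = np.stack([cm.data[m] for cm in maps])
    corr = np.corrcoef(vals) if len(maps) > 1 else np.ones((1, 1))
    report = pd.DataFrame(corr, index=names, columns=names)
    return WindowSensitivityResult(maps=maps, pairwise_correlations=report)
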