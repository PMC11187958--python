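"""Temporal filtering and nuisance regression for voxel time series.

Every voxel series is pushed through one linear projection stage before any
connectivity estimate: principal components extracted from a noise region
(CompCor-style anatomical nuisance regression) are regressed out, and the
series is band-pass filtered to the resting-state band of interest
(0.015-0.1 Hz by default).  The filter is a zero-phase frequency-domain
window: FFT, zero every out-of-band bin, inverse FFT.  Nuisance regressors
are themselves band-passed before regression so the regression step cannot
reintroduce out-of-band power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MIN_TIMEPOINTS = 16

__all__ = [
    "BandSpec",
    "NuisanceSet",
    "bandpass",
    "compcor_components",
    "regress_out",
    "denoise_image",
]


@dataclass(frozen=True)
class BandSpec:
    """Pass band in Hz. Valid only when ``f_low < f_high < 1/(2*TR)``."""

    f_low: float = 0.015
    f_high: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band must satisfy 0 < f_low < f_high, got [{self.f_low}, {self.f_high}]"
            )

    def validate_for_tr(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.f_high >= nyquist:
            raise ValueError(
                f"f_high={self.f_high} Hz is at or above the Nyquist frequency "
                f"{nyquist:.4g} Hz for TR={tr_seconds} s"
            )


@dataclass
class NuisanceSet:
    """Labelled nuisance regressor time series, one column per regressor."""

    regressors: np.ndarray  # (T, k)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must form a (T, k) matrix")
        if not self.labels:
            self.labels = [f"nuisance_{i}" for i in range(self.regressors.shape[1])]
        if len(self.labels) != self.regressors.shape[1]:
            raise ValueError("one label per regressor column required")
        norms = np.abs(self.regressors).max(axis=0, initial=0.0)
        if self.regressors.shape[1] and np.any(norms == 0.0):
            dead = [l for l, nz in zip(self.labels, norms) if nz == 0.0]
            raise ValueError(f"all-zero nuisance regressors: {dead}")

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


def bandpass(series: np.ndarray, tr_seconds: float, band: BandSpec | None = None,
             axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass filter along ``axis``.

    Implemented as a hard spectral window on the real FFT: bins with
    ``f_low <= f <= f_high`` (endpoints inclusive) are retained unchanged,
    every other bin including DC is zeroed, so in-band amplitudes are exact
    and the output has zero mean.
    """
    band = band or BandSpec()
    band.validate_for_tr(tr_seconds)
    x = np.asarray(series, dtype=float)
    T = x.shape[axis]
    if T < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} timepoints, got {T}")
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = keep.size
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=T, axis=axis)


def compcor_components(noise_series: np.ndarray, n_components: int = 5) -> NuisanceSet:
    """Principal-component nuisance series from a noise-region (T, V) matrix.

    Voxel series are standardized (zero-variance voxels dropped) and the top
    ``n_components`` left singular vectors are returned, each scaled to unit
    sample variance.  Components are mutually orthogonal by construction.
    """
    X = np.asarray(noise_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("noise_series must be a (T, V) matrix")
    T = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all noise-region voxels have zero variance")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    V = X.shape[1]
    if not (1 <= n_components <= V):
        raise ValueError(
            f"n_components={n_components} outside [1, {V}] (non-degenerate voxels)"
        )
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    comps = U[:, :n_components] * np.sqrt(T - 1)
    labels = [f"compcor_{i}" for i in range(n_components)]
    return NuisanceSet(regressors=comps, labels=labels)


def _collinear_labels(design: np.ndarray, labels: list[str]) -> list[str]:
    # greedy scan: flag each column that fails to increase the design rank
    bad, cols = [], []
    rank = 0
    for j in range(design.shape[1]):
        cols.append(design[:, j])
        r = np.linalg.matrix_rank(np.column_stack(cols))
        if r == rank:
            bad.append(labels[j])
            cols.pop()
        else:
            rank = r
    return bad


def regress_out(series: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Least-squares residual of ``series`` on intercept + nuisance regressors.

    ``series`` may be 1-D (length T) or 2-D (T, V); the residual is orthogonal
    to every regressor and to the constant.
    """
    y = np.asarray(series, dtype=float)
    T = y.shape[0]
    if nuisance.n_timepoints != T:
        raise ValueError(
            f"regressor length {nuisance.n_timepoints} != series length {T}"
        )
    design = np.column_stack([np.ones(T), nuisance.regressors])
    labels = ["intercept", *nuisance.labels]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient nuisance design; collinear: {_collinear_labels(design, labels)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def denoise_image(data4d: np.ndarray, noise_mask: np.ndarray, tr_seconds: float,
                  band: BandSpec | None = None, n_compcor: int = 5) -> np.ndarray:
    """Full denoising stage for a 4-D (x, y, z, T) array.

    Order: CompCor components from the noise region, band-pass of both the
    components and every voxel series, then regression of the (filtered)
    components out of the (filtered) voxels — a single linear projection.
    Returns a new array of the same shape.
    """
    band = band or BandSpec()
    data4d = np.asarray(data4d, dtype=float)
    noise = np.asarray(noise_mask).astype(bool)
    T = data4d.shape[-1]
    flat = data4d.reshape(-1, T).T  # (T, Nvox)
    comps = compcor_components(flat[:, noise.ravel()], n_components=n_compcor)
    comps = NuisanceSet(
        regressors=bandpass(comps.regressors, tr_seconds, band, axis=0),
        labels=comps.labels,
    )
    filt = bandpass(flat, tr_seconds, band, axis=0)
    clean = regress_out(filt, comps)
    logger.debug("denoised %d voxels with %d CompCor components", flat.shape[1],
                 comps.n_regressors)
    return clean.T.reshape(data4d.shape)
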