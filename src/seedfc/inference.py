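"""Group-level permutation inference with TFCE and FWER correction.

Pre/post connectivity-change maps are tested voxelwise with OLS t statistics
(age and sex as covariates of no interest), enhanced with threshold-free
cluster enhancement (TFCE), and corrected for family-wise error with the
permutation distribution of the maximum TFCE statistic.  The permutation
scheme is Freedman-Lane: residuals from the nuisance-only model are
sign-flipped (paired pre/post test) or subject-permuted (clinical-change
correlation) and the nuisance fit is added back before the statistic is
recomputed.  Positive and negative tails are enhanced separately; the null
maximum is taken over both tails, so the corrected p-values control FWER
across the whole map and both directions jointly.

Also provides the scalar statistics used for cohort description: paired and
two-sample t tests, Pearson chi-square on 2x2 tables, partial correlations
controlling for covariates, percent-change scores, +/-3 SD outlier
screening, and remission classification (HDRS <= 7 after treatment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .connectivity import ConnectivityMap

logger = logging.getLogger(__name__)

__all__ = [
    "TFCEParams",
    "DesignMatrix",
    "InferenceResult",
    "percent_change",
    "remove_outliers",
    "paired_change_map",
    "permutation_ttest_map",
    "permutation_corr_map",
    "tfce_enhance",
    "fwer_pvalues",
    "partial_correlation",
    "paired_ttest",
    "two_sample_t",
    "chi_square_2x2",
    "classify_remitters",
]


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings: height exponent H, extent exponent E, number of height
    steps for the discrete integral, and voxel neighbourhood (6/18/26)."""

    height_power: float = 2.0
    extent_power: float = 0.5
    n_height_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.height_power <= 0:
            raise ValueError("height_power must be > 0")
        if self.extent_power < 0:
            raise ValueError("extent_power must be >= 0")
        if self.n_height_steps < 10:
            raise ValueError("n_height_steps must be >= 10")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


_CSR_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _neighbor_csr(shape: tuple[int, int, int], connectivity: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index neighbour lists in CSR form for a 3-D grid."""
    key = (shape, connectivity)
    if key in _CSR_CACHE:
        return _CSR_CACHE[key]
    idx = np.arange(int(np.prod(shape)), dtype=np.int64).reshape(shape)
    src_all, dst_all = [], []
    for dx, dy, dz in _neighbor_offsets(connectivity):
        sl_src = tuple(slice(max(0, -d), s - max(0, d)) for d, s in zip((dx, dy, dz), shape))
        sl_dst = tuple(slice(max(0, d), s - max(0, -d)) for d, s in zip((dx, dy, dz), shape))
        src_all.append(idx[sl_src].ravel())
        dst_all.append(idx[sl_dst].ravel())
    src = np.concatenate(src_all)
    dst = np.concatenate(dst_all)
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    counts = np.bincount(src, minlength=idx.size)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    _CSR_CACHE[key] = (indptr, indices)
    return indptr, indices


@njit(cache=True)
def _uf_find(parent, v):
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        parent[v], v = root, parent[v]
    return root


@njit(cache=True)
def _tfce_kernel(values, order, indptr, indices, n_steps, E, H):
    """Discrete TFCE integral via incremental union-find.

    Thresholds h = i*dh, i = n_steps..1, dh = max/n_steps, descend; at each
    threshold the suprathreshold voxels (value >= h) are merged into
    connected components and every suprathreshold voxel accumulates
    size(component)^E * h^H * dh — identical to labelling the mask at every
    threshold, but done in one pass.
    """
    N = values.size
    out = np.zeros(N)
    vmax = values[order[0]]
    if vmax <= 0.0:
        return out
    dh = vmax / n_steps
    parent = np.empty(N, np.int64)
    size = np.zeros(N, np.int64)
    active = np.zeros(N, np.uint8)
    act_list = np.empty(N, np.int64)
    n_act = 0
    ptr = 0
    for step in range(n_steps, 0, -1):
        h = step * dh
        while ptr < N and values[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            active[v] = 1
            act_list[n_act] = v
            n_act += 1
            for jj in range(indptr[v], indptr[v + 1]):
                u = indices[jj]
                if active[u] == 1:
                    ru = _uf_find(parent, u)
                    rv = _uf_find(parent, v)
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
            ptr += 1
        inc = (h ** H) * dh
        for ii in range(n_act):
            v = act_list[ii]
            out[v] += (size[_uf_find(parent, v)] ** E) * inc
    return out


def _tfce_one_tail(values_flat: np.ndarray, shape: tuple[int, int, int],
                   params: TFCEParams) -> np.ndarray:
    if values_flat.max(initial=0.0) <= 0.0:
        return np.zeros_like(values_flat)
    indptr, indices = _neighbor_csr(shape, params.connectivity)
    order = np.argsort(-values_flat, kind="stable")
    return _tfce_kernel(values_flat, order, indptr, indices,
                        params.n_height_steps, params.extent_power,
                        params.height_power)


def tfce_enhance(stat_map: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Signed TFCE map: positive values enhanced as-is, negative values
    enhanced on the negated map and re-negated.  An all-zero map maps to an
    all-zero map."""
    params = params or TFCEParams()
    stat = np.asarray(stat_map, dtype=float)
    if stat.ndim != 3:
        raise ValueError("stat_map must be 3-D")
    if not np.isfinite(stat).all():
        raise ValueError("stat_map contains non-finite values")
    shape = stat.shape
    pos = _tfce_one_tail(np.maximum(stat, 0.0).ravel(), shape, params)
    neg = _tfce_one_tail(np.maximum(-stat, 0.0).ravel(), shape, params)
    return (pos - neg).reshape(shape)


# ---------------------------------------------------------------------------
# Designs and voxelwise OLS t statistics
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with labels; must have full column rank."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("one label per design column required")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError(f"rank-deficient design: columns {self.labels}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    """Covariates of no interest as a demeaned (n, k) array; k may be 0."""
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, pd.DataFrame):
        Z = covariates.to_numpy(dtype=float)
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n and Z.shape[1] == n:
            Z = Z.T
    if Z.shape[0] != n:
        raise ValueError(f"covariates have {Z.shape[0]} rows, expected {n}")
    return Z - Z.mean(axis=0)


def _tstat(Y: np.ndarray, X: np.ndarray, col: int,
           XtXinv: np.ndarray | None = None) -> np.ndarray:
    """t statistic for design column ``col``, vectorized over the columns of Y."""
    n, p = X.shape
    if XtXinv is None:
        XtXinv = np.linalg.inv(X.T @ X)
    B = XtXinv @ (X.T @ Y)
    R = Y - X @ B
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = np.einsum("ij,ij->j", R, R) / dof
    se2 = s2 * XtXinv[col, col]
    t = np.zeros(Y.shape[1])
    ok = se2 > 0
    t[ok] = B[col, ok] / np.sqrt(se2[ok])
    return t


# ---------------------------------------------------------------------------
# Change maps and permutation tests
# ---------------------------------------------------------------------------

def _map_array(m) -> np.ndarray:
    return m.data if isinstance(m, ConnectivityMap) else np.asarray(m, dtype=float)


def _stack_deltas(delta_maps) -> np.ndarray:
    if isinstance(delta_maps, np.ndarray):
        return np.asarray(delta_maps, dtype=float)
    return np.stack([_map_array(d) for d in delta_maps])


def paired_change_map(pre_maps, post_maps) -> np.ndarray:
    """Per-subject post-minus-pre maps, stacked as (n_subjects, x, y, z).

    Accepts lists of ConnectivityMap (subject ids must match pairwise) or of
    plain 3-D arrays in matched order.
    """
    if len(pre_maps) != len(post_maps):
        raise ValueError("pre and post map lists differ in length")
    deltas = []
    for pre, post in zip(pre_maps, post_maps):
        if isinstance(pre, ConnectivityMap) and isinstance(post, ConnectivityMap):
            if pre.subject_id != post.subject_id:
                raise ValueError(
                    f"unmatched subjects: {pre.subject_id!r} vs {post.subject_id!r}")
        a = _map_array(pre)
        b = _map_array(post)
        if a.shape != b.shape:
            raise ValueError("pre/post map shapes differ")
        deltas.append(b - a)
    return np.stack(deltas)


@dataclass
class InferenceResult:
    """Voxelwise statistic, signed TFCE, and FWER-corrected p maps."""

    stat_map: np.ndarray
    tfce_map: np.ndarray
    p_map: np.ndarray
    n_permutations: int
    seed: int
    excluded_subjects: list[str] = field(default_factory=list)
    null_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = self.p_map[np.isfinite(self.p_map)]
        if p.size and (p.min() <= 0 or p.max() > 1):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (1.0 + self.n_permutations)


def fwer_pvalues(observed_tfce: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    """FWER-corrected p: p_v = (1 + #{null maxima >= observed_v}) / (1 + n_perm).

    The +1 terms add the identity permutation to the null, so the smallest
    attainable p is 1/(1 + n_perm).
    """
    null_max = np.asarray(null_max, dtype=float).ravel()
    if null_max.size == 0:
        raise ValueError("empty null distribution")
    obs = np.asarray(observed_tfce, dtype=float)
    srt = np.sort(null_max)
    # exceedances = #{null >= obs} via sorted search
    exceed = null_max.size - np.searchsorted(srt, obs, side="left")
    return (1.0 + exceed) / (1.0 + null_max.size)


def _finalize(t_flat, mask, params, null_max, n_perm, seed, excluded):
    shape = mask.shape
    tfce_obs = tfce_enhance(_unflatten(t_flat, mask), params)
    p = fwer_pvalues(np.abs(tfce_obs[mask]), null_max)
    stat = _unflatten(t_flat, mask)
    p_map = np.ones(shape)
    p_map[mask] = p
    return InferenceResult(stat_map=stat, tfce_map=tfce_obs, p_map=p_map,
                           n_permutations=n_perm, seed=seed,
                           excluded_subjects=list(excluded), null_max=null_max)


def _unflatten(flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.shape)
    out[mask] = flat
    return out


def _resolve_mask(delta: np.ndarray, mask) -> np.ndarray:
    if mask is None:
        return np.ones(delta.shape[1:], dtype=bool)
    m = mask.data if hasattr(mask, "data") else np.asarray(mask)
    return m.astype(bool)


def permutation_ttest_map(delta_maps, covariates=None, params: TFCEParams | None = None,
                          n_perm: int = 5000, seed: int = 0, mask=None,
                          excluded_subjects: list[str] | None = None) -> InferenceResult:
    """One-sample (paired-change) permutation test with TFCE + max-stat FWER.

    Voxelwise model: delta ~ 1 + age + sex; the t statistic of the intercept
    tests the mean change.  The null is generated by sign-flipping the
    residuals of the nuisance-only model and adding the nuisance fit back
    (Freedman-Lane with a sign-flip group, valid for symmetric paired errors).
    """
    params = params or TFCEParams()
    delta = _stack_deltas(delta_maps)
    n = delta.shape[0]
    if n < 8:
        raise ValueError(f"permutation test needs >= 8 subjects, got {n}")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    m = _resolve_mask(delta, mask)
    Y = delta.reshape(n, -1)[:, m.ravel()]
    Z = _covariate_matrix(covariates, n)
    design = DesignMatrix(np.column_stack([np.ones(n), Z]),
                          ["intercept"] + [f"nuisance_{i}" for i in range(Z.shape[1])])
    X = design.matrix
    XtXinv = np.linalg.inv(X.T @ X)

    if Z.shape[1]:
        gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ gamma
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted

    t_obs = _tstat(Y, X, 0, XtXinv)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for j in range(n_perm):
        signs = rng.integers(0, 2, size=n) * 2.0 - 1.0
        Yp = signs[:, None] * resid + fitted
        tp = _tstat(Yp, X, 0, XtXinv)
        null_max[j] = np.abs(tfce_enhance(_unflatten(tp, m), params)).max()
    return _finalize(t_obs, m, params, null_max, n_perm, seed,
                     excluded_subjects or [])


def permutation_corr_map(delta_maps, clinical_pc, covariates=None,
                         params: TFCEParams | None = None, n_perm: int = 5000,
                         seed: int = 0, mask=None,
                         excluded_subjects: list[str] | None = None) -> InferenceResult:
    """Voxelwise clinical-change correlation test with TFCE + max-stat FWER.

    Model: delta ~ 1 + percent_change + age + sex; the t statistic of the
    percent-change slope is tested against a Freedman-Lane null (permute the
    nuisance-model residuals of the data across subjects, add back the
    nuisance fit).  Outlier screening of ``clinical_pc`` is the caller's
    responsibility (see :func:`remove_outliers`).
    """
    params = params or TFCEParams()
    delta = _stack_deltas(delta_maps)
    pc = np.asarray(clinical_pc, dtype=float).ravel()
    n = delta.shape[0]
    if pc.size != n:
        raise ValueError(f"{pc.size} clinical scores for {n} maps")
    if np.ptp(pc) == 0:
        raise ValueError("clinical percent-change vector is constant")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    m = _resolve_mask(delta, mask)
    Y = delta.reshape(n, -1)[:, m.ravel()]
    Z = _covariate_matrix(covariates, n)
    Z0 = np.column_stack([np.ones(n), Z])  # nuisance incl. intercept
    design = DesignMatrix(
        np.column_stack([np.ones(n), pc - pc.mean(), Z]),
        ["intercept", "clinical_pc"] + [f"nuisance_{i}" for i in range(Z.shape[1])],
    )
    X = design.matrix
    XtXinv = np.linalg.inv(X.T @ X)

    gamma, *_ = np.linalg.lstsq(Z0, Y, rcond=None)
    fitted = Z0 @ gamma
    resid = Y - fitted

    t_obs = _tstat(Y, X, 1, XtXinv)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(n)
        Yp = resid[perm] + fitted
        tp = _tstat(Yp, X, 1, XtXinv)
        null_max[j] = np.abs(tfce_enhance(_unflatten(tp, m), params)).max()
    return _finalize(t_obs, m, params, null_max, n_perm, seed,
                     excluded_subjects or [])


# ---------------------------------------------------------------------------
# Clinical-score and demographic statistics
# ---------------------------------------------------------------------------

def percent_change(pre, post):
    """100 * (post - pre) / pre; elementwise for arrays; pre must be nonzero."""
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if np.any(pre_arr == 0):
        raise ValueError("percent change undefined for pre = 0")
    out = 100.0 * (post_arr - pre_arr) / pre_arr
    return float(out) if out.ndim == 0 else out


def remove_outliers(values, k: float = 3.0) -> np.ndarray:
    """Indices of values within k sample SDs of the mean (single pass).

    Mean and SD are computed once over all input values; with zero SD every
    index is retained.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.arange(v.size)
    keep = np.abs(v - v.mean()) <= k * sd
    return np.flatnonzero(keep)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates (+ intercept)
    from both; p from the t distribution with n - k - 2 df."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    C = _covariate_matrix(covariates, n)
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    design = DesignMatrix(np.column_stack([np.ones(n), C]),
                          ["intercept"] + [f"cov_{i}" for i in range(k)])
    D = design.matrix
    bx, *_ = np.linalg.lstsq(D, x, rcond=None)
    by, *_ = np.linalg.lstsq(D, y, rcond=None)
    rx, ry = x - D @ bx, y - D @ by
    # a variable fully explained by the covariates has no residual left to
    # correlate: report r = 0 instead of correlating rounding noise
    tol_x = 1e-10 * max(float(np.abs(x - x.mean()).max()), 1e-300) ** 2 * n
    tol_y = 1e-10 * max(float(np.abs(y - y.mean()).max()), 1e-300) ** 2 * n
    if (rx @ rx) <= tol_x or (ry @ ry) <= tol_y:
        return 0.0, 1.0
    r = float(np.clip((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)), -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def paired_ttest(pre, post) -> tuple[float, int, float]:
    """Paired t test of post vs pre: t = mean(d)/(SD(d)/sqrt(n)), d = post - pre."""
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise ValueError("pre and post must be matched")
    n = pre.size
    if n < 3:
        raise ValueError("paired t test needs n >= 3")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def _as_summary(group) -> tuple[int, float, float]:
    if isinstance(group, tuple) and len(group) == 3:
        n, mean, sd = group
        return int(n), float(mean), float(sd)
    arr = np.asarray(group, dtype=float).ravel()
    return arr.size, float(arr.mean()), float(arr.std(ddof=1))


def two_sample_t(group_a, group_b, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sample t test from raw values or (n, mean, sd) summaries.

    Pooled-variance by default; set ``equal_var=False`` for Welch.
    Returns (t, df, two-sided p).
    """
    na, ma, sa = _as_summary(group_a)
    nb, mb, sb = _as_summary(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    if sa == 0 and sb == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=equal_var)
    df = na + nb - 2 if equal_var else float(res.df) if hasattr(res, "df") else na + nb - 2
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero row or column sum; expected counts undefined")
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof), float(p)


def classify_remitters(hdrs_post, threshold: float = 7.0) -> list[bool]:
    """Remission flags: post-treatment HDRS score <= threshold (default 7)."""
    scores = np.asarray(hdrs_post, dtype=float).ravel()
    if (scores < 0).any():
        raise ValueError("HDRS scores cannot be negative")
    return [bool(s <= threshold) for s in scores]
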