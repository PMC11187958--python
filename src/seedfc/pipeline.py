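"""Configuration-driven orchestration of the full analysis.

Three modes:

* ``simulate`` — generate a synthetic cohort and write it to disk;
* ``analyze`` — run the full pipeline on a cohort directory: denoise,
  extract seeds, build sFC/dFCv maps per session, form pre-to-post change
  maps, and run the permutation tests (paired change, HDRS and SHAPS
  percent-change correlations) with TFCE + FWER correction;
* ``calibrate`` — estimate empirical type-I error and power over replicate
  synthetic cohorts.

Every run writes a machine-readable JSON log capturing the configuration and
seeds, statistic/TFCE/p maps as NIfTI, and TSV cluster tables; identical
configurations give byte-identical TSV output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from . import synthetic
from .connectivity import (ConnectivityMap, WindowSpec, check_min_window,
                           dfcv_map, static_fc_map)
from .denoise import BandSpec, denoise_image
from .inference import (InferenceResult, TFCEParams, paired_change_map,
                        percent_change, permutation_corr_map,
                        permutation_ttest_map, remove_outliers)
from .seeds import extract_seed
from .synthetic import (Cohort, CohortSpec, RoiMask, TimeSeriesImage,
                        default_cohort_spec, generate_cohort, read_cohort,
                        write_cohort)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_analysis",
    "run_calibration",
    "run",
    "concatenate_runs",
    "cluster_table",
]


@dataclass
class RunConfig:
    """Single-document configuration; CLI flags override file keys."""

    mode: str = "analyze"
    data_dir: str = "cohort"
    out_dir: str = "results"
    band: BandSpec = field(default_factory=BandSpec)
    window_trs: tuple[int, ...] = (84,)
    step_trs: int = 1
    taper: str = "hamming"
    tfce: TFCEParams = field(default_factory=TFCEParams)
    n_perm: int = 5000
    seed: int = 0
    outlier_k: float = 3.0
    n_compcor: int = 5
    covariate_columns: tuple[str, ...] = ("age", "sex")
    clinical_columns: tuple[str, ...] = ("hdrs", "shaps")
    seed_masks: tuple[str, ...] = ("seed",)
    brain_mask: str = "brain"
    noise_mask: str = "noise_roi"
    alpha: float = 0.05
    tr_seconds: float = 0.8  # re-validated against the image TR at run time
    # simulate/calibrate only
    n_subjects: int = 12
    n_timepoints: int = 300
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    n_replicates: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "calibrate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        self.window_trs = tuple(int(w) for w in self.window_trs)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        for w in self.window_trs:
            check_min_window(WindowSpec(w, self.step_trs, self.taper),
                             self.tr_seconds, self.band)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "band" in raw and isinstance(raw["band"], dict):
            raw["band"] = BandSpec(**raw["band"])
        if "tfce" in raw and isinstance(raw["tfce"], dict):
            raw["tfce"] = TFCEParams(**raw["tfce"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def concatenate_runs(images: list[TimeSeriesImage]) -> TimeSeriesImage:
    """Concatenate same-subject runs along time (each run demeaned first, so
    run-specific offsets do not masquerade as slow signal)."""
    if not images:
        raise ValueError("no runs to concatenate")
    trs = {img.tr_seconds for img in images}
    if len(trs) > 1:
        raise ValueError("runs have differing TRs")
    parts = [img.data - img.data.mean(axis=-1, keepdims=True) for img in images]
    return TimeSeriesImage(np.concatenate(parts, axis=-1), images[0].tr_seconds,
                           subject_id=images[0].subject_id,
                           session=images[0].session)


def cluster_table(result: InferenceResult, alpha: float, connectivity: int,
                  voxel_size_mm: float) -> pd.DataFrame:
    """Connected components of corrected p < alpha: voxel count, peak |t|,
    peak location in 0-based voxel indices and scanner mm."""
    sig = result.p_map < alpha
    structure = ndi.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    labels, n_clusters = ndi.label(sig, structure=structure)
    rows = []
    for c in range(1, n_clusters + 1):
        in_c = labels == c
        stats_abs = np.abs(result.stat_map) * in_c
        peak = np.unravel_index(np.argmax(stats_abs), labels.shape)
        rows.append({
            "cluster": c,
            "n_voxels": int(in_c.sum()),
            "peak_t": round(float(result.stat_map[peak]), 6),
            "peak_p_fwer": round(float(result.p_map[peak]), 6),
            "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
            "peak_x_mm": peak[0] * voxel_size_mm,
            "peak_y_mm": peak[1] * voxel_size_mm,
            "peak_z_mm": peak[2] * voxel_size_mm,
        })
    return pd.DataFrame(rows, columns=[
        "cluster", "n_voxels", "peak_t", "peak_p_fwer",
        "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    ])


def _save_map(path: Path, data: np.ndarray, voxel_size_mm: float) -> None:
    synthetic._save_nifti(path, data.astype(np.float32), voxel_size_mm)


def run_simulate(config: RunConfig, spec: CohortSpec | None = None) -> dict:
    """Generate a synthetic cohort and write it under ``config.data_dir``."""
    spec = spec or default_cohort_spec(
        n_subjects=config.n_subjects,
        n_timepoints=config.n_timepoints,
        grid_shape=config.grid_shape,
        rng_seed=config.seed,
    )
    spec.validate_for_window(max(config.window_trs))
    cohort = generate_cohort(spec)
    return write_cohort(cohort, config.data_dir)


def _percent_change_table(table: pd.DataFrame, clinical_cols) -> pd.DataFrame:
    wide = table.pivot_table(index="subject_id", columns="session",
                             values=list(clinical_cols), aggfunc="first")
    base = table[table.session == "pre"].set_index("subject_id")
    out = pd.DataFrame(index=wide.index)
    for col in clinical_cols:
        out[f"pc_{col}"] = percent_change(wide[(col, "pre")], wide[(col, "post")])
    for cov in ("age", "sex"):
        out[cov] = base[cov]
    return out.sort_index()


def _session_maps(images, masks, config: RunConfig, tr: float,
                  kinds: tuple[str, ...] = ("sfc", "dfcv"),
                  ) -> dict[tuple[str, str, str], list[ConnectivityMap]]:
    """kind-keyed connectivity maps: (seed, kind, session) -> map per subject list."""
    brain = masks[config.brain_mask]
    noise = masks[config.noise_mask]
    wspec = WindowSpec(config.window_trs[0], config.step_trs, config.taper)
    check_min_window(wspec, tr, config.band)
    out: dict[tuple[str, str, str], list[ConnectivityMap]] = {}
    for pre_img, post_img in images:
        for img in (pre_img, post_img):
            clean = TimeSeriesImage(
                denoise_image(img.data, noise.data, tr, config.band, config.n_compcor),
                tr, subject_id=img.subject_id, session=img.session)
            for seed_name in config.seed_masks:
                seed = extract_seed(clean, masks[seed_name])
                if "sfc" in kinds:
                    out.setdefault((seed_name, "sfc", img.session), []).append(
                        static_fc_map(seed, clean, brain))
                if "dfcv" in kinds:
                    out.setdefault((seed_name, "dfcv", img.session), []).append(
                        dfcv_map(seed, clean, brain, wspec))
    return out


def run_analysis(config: RunConfig) -> dict:
    """Full analysis on a cohort directory; returns the result bundle.

    Per seed x {sFC, dFCv}: the paired pre/post permutation test and one
    permutation correlation test per clinical score, each written as NIfTI
    maps plus a TSV cluster table.  Inputs are never modified.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, masks, table = read_cohort(config.data_dir)
    tr = images[0][0].tr_seconds
    vs = json.loads((Path(config.data_dir) / "manifest.json").read_text())["voxel_size_mm"]

    maps = _session_maps(images, masks, config, tr)
    pc = _percent_change_table(table, config.clinical_columns)
    subject_ids = [pair[0].subject_id for pair in images]
    covs = pc.loc[subject_ids, list(config.covariate_columns)]

    bundle: dict[str, dict] = {}
    deltas: dict[str, np.ndarray] = {}
    summaries = []
    for seed_name in config.seed_masks:
        for kind in ("sfc", "dfcv"):
            delta = paired_change_map(maps[(seed_name, kind, "pre")],
                                      maps[(seed_name, kind, "post")])
            deltas[f"{seed_name}_{kind}"] = delta
            analyses: dict[str, InferenceResult] = {}
            analyses["paired"] = permutation_ttest_map(
                delta, covs, config.tfce, config.n_perm, config.seed,
                mask=masks[config.brain_mask])
            for col in config.clinical_columns:
                pcv = pc.loc[subject_ids, f"pc_{col}"].to_numpy()
                missing = np.flatnonzero(~np.isfinite(pcv))
                keep = np.flatnonzero(np.isfinite(pcv))
                keep = keep[remove_outliers(pcv[keep], config.outlier_k)]
                excluded = [subject_ids[i] for i in range(len(subject_ids)) if i not in keep]
                if missing.size or excluded:
                    logger.info("%s/%s/%s: excluded subjects %s", seed_name, kind, col, excluded)
                analyses[f"corr_{col}"] = permutation_corr_map(
                    delta[keep], pcv[keep], covs.iloc[keep], config.tfce,
                    config.n_perm, config.seed, mask=masks[config.brain_mask],
                    excluded_subjects=excluded)
            for name, res in analyses.items():
                stem = f"{seed_name}_{kind}_{name}"
                _save_map(out_dir / f"{stem}_tstat.nii", res.stat_map, vs)
                _save_map(out_dir / f"{stem}_tfce.nii", res.tfce_map, vs)
                _save_map(out_dir / f"{stem}_pfwer.nii", res.p_map, vs)
                ct = cluster_table(res, config.alpha, config.tfce.connectivity, vs)
                ct.insert(0, "analysis", stem)
                ct.to_csv(out_dir / f"{stem}_clusters.tsv", sep="\t", index=False,
                          float_format="%.6g")
                summaries.append(ct)
            bundle[f"{seed_name}_{kind}"] = analyses

    nonempty = [s for s in summaries if not s.empty]
    summary = pd.concat(nonempty, ignore_index=True) if nonempty else pd.DataFrame(
        columns=["analysis", "cluster", "n_voxels", "peak_t", "peak_p_fwer",
                 "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm"])
    summary.to_csv(out_dir / "cluster_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    run_log = {
        "config": config.to_dict(),
        "tr_seconds": tr,
        "n_subjects": len(images),
        "analyses": {
            key: {name: {"n_permutations": r.n_permutations, "seed": r.seed,
                         "excluded_subjects": r.excluded_subjects,
                         "min_p": float(r.p_map.min())}
                  for name, r in group.items()}
            for key, group in bundle.items()
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    logger.info("analysis complete: %d analyses -> %s", sum(len(g) for g in bundle.values()),
                out_dir)
    return {"results": bundle, "deltas": deltas, "subject_ids": subject_ids,
            "clinical": pc, "summary": summary, "log": run_log}


def _null_spec(config: RunConfig, rep_seed: int) -> CohortSpec:
    """Cohort with no pre-to-post change and no clinical-coupling link."""
    base = default_cohort_spec(
        n_subjects=config.n_subjects, n_timepoints=config.n_timepoints,
        grid_shape=config.grid_shape, rng_seed=rep_seed)
    cpl = {"pre": synthetic.CouplingSpec(static_r=0.3),
           "post": synthetic.CouplingSpec(static_r=0.3)}
    targets = tuple(dataclasses.replace(t, coupling=cpl) for t in base.target_regions)
    cm = dataclasses.replace(base.clinical_model, slope=0.0)
    return dataclasses.replace(base, target_regions=targets, clinical_model=cm)


def _cohort_delta_sfc(cohort: Cohort, config: RunConfig) -> tuple[np.ndarray, pd.DataFrame]:
    maps = _session_maps(cohort.images, cohort.masks, config,
                         cohort.spec.tr_seconds, kinds=("sfc",))
    seed_name = config.seed_masks[0]
    delta = paired_change_map(maps[(seed_name, "sfc", "pre")],
                              maps[(seed_name, "sfc", "post")])
    covs = cohort.table[cohort.table.session == "pre"].set_index("subject_id")
    covs = covs.loc[[p[0].subject_id for p in cohort.images],
                    list(config.covariate_columns)]
    return delta, covs


def run_calibration(config: RunConfig, effect: bool = False) -> dict:
    """Empirical FWER (null cohorts) or power (planted-effect cohorts) of the
    paired TFCE max-stat test over ``config.n_replicates`` replicates."""
    if config.n_replicates < 20:
        logger.warning("only %d replicates; calibration estimate will be coarse",
                       config.n_replicates)
    rng = np.random.default_rng(config.seed)
    detections = 0
    for rep in range(config.n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spec = _null_spec(config, rep_seed)
        if effect:
            cpl = {"pre": synthetic.CouplingSpec(static_r=0.2),
                   "post": synthetic.CouplingSpec(static_r=0.6)}
            targets = tuple(dataclasses.replace(t, coupling=cpl)
                            for t in spec.target_regions)
            spec = dataclasses.replace(spec, target_regions=targets)
        cohort = generate_cohort(spec)
        delta, covs = _cohort_delta_sfc(cohort, config)
        res = permutation_ttest_map(delta, covs, config.tfce, config.n_perm,
                                    seed=rep_seed,
                                    mask=cohort.masks[config.brain_mask])
        if res.p_map.min() < config.alpha:
            detections += 1
    rate = detections / config.n_replicates
    kind = "power" if effect else "fwer"
    report = {
        "kind": kind, "rate": rate, "n_replicates": config.n_replicates,
        "n_perm": config.n_perm, "alpha": config.alpha,
        "n_subjects": config.n_subjects, "seed": config.seed,
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([report]).to_csv(out_dir / f"calibration_{kind}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    logger.info("calibration (%s): rate=%.3f over %d replicates", kind, rate,
                config.n_replicates)
    return report


def run(config: RunConfig) -> dict:
    """Dispatch on ``config.mode``."""
    if config.mode == "simulate":
        return run_simulate(config)
    if config.mode == "analyze":
        return run_analysis(config)
    return run_calibration(config)
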