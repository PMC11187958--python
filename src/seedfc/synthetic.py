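"""Synthetic two-session resting-state cohorts with planted connectivity.

The generator emulates a pre/post-treatment depression cohort: per subject
and session a 4-D voxel time-series image in which a small seed region
carries a shared band-limited signal, designated target regions are coupled
to that signal with a stationary and/or sinusoidally amplitude-modulated
correlation, and everything else is independent band-limited noise.  The
accompanying clinical table links percent change in HDRS (depression) and
SHAPS (hedonic capacity) scores to each subject's planted coupling change,
so every downstream stage of the pipeline has ground truth to recover.

Coupling is variance-preserving mixing: a target voxel is
``y_t = a_t * s_t + sqrt(1 - a_t**2) * eps_t`` with instantaneous coupling
``a_t = static_r + mod_amplitude * sin(2*pi*t*TR / mod_period)``, so the
planted static correlation is ``static_r`` and sliding-window variability
grows with ``mod_amplitude``.  All noise sources are band-limited to the
analysis band and standardized, so the synthetic data already respect the
band the denoising stage applies.

Generation is a pure function of the spec: the random stream for subject
``i`` is derived from ``(rng_seed, i, stream)`` so identical specs and
indices give bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .denoise import BandSpec, bandpass

logger = logging.getLogger(__name__)

SESSIONS = ("pre", "post")
_SESSION_CODE = {"pre": 0, "post": 1}
# subject-level stream ids (third entry of the SeedSequence key)
_STREAM_COUPLING = 2
_STREAM_CLINICAL = 3

__all__ = [
    "CouplingSpec",
    "Region",
    "TargetRegion",
    "ClinicalModel",
    "AgeModel",
    "CohortSpec",
    "TimeSeriesImage",
    "RoiMask",
    "Cohort",
    "default_cohort_spec",
    "generate_subject_session",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Seed-target coupling for one session.

    ``static_r`` is the stationary correlation, ``mod_amplitude`` the
    amplitude of a slow sinusoidal modulation of the instantaneous coupling
    with period ``mod_period_seconds``.
    """

    static_r: float = 0.0
    mod_amplitude: float = 0.0
    mod_period_seconds: float = 120.0

    def __post_init__(self) -> None:
        if not -1.0 < self.static_r < 1.0:
            raise ValueError(f"static_r must lie in (-1, 1), got {self.static_r}")
        if self.mod_amplitude < 0:
            raise ValueError("mod_amplitude must be >= 0")
        if self.mod_period_seconds <= 0:
            raise ValueError("mod_period_seconds must be positive")
        if abs(self.static_r) + self.mod_amplitude > 0.99:
            raise ValueError(
                "|static_r| + mod_amplitude must be <= 0.99 to keep the "
                "instantaneous coupling inside (-1, 1)"
            )


@dataclass(frozen=True)
class Region:
    """Named set of voxel indices (0-based (i, j, k) triples)."""

    name: str
    voxels: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if not self.voxels:
            raise ValueError(f"region {self.name!r} has no voxels")
        object.__setattr__(self, "voxels", tuple(tuple(int(c) for c in v) for v in self.voxels))

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arr = np.asarray(self.voxels)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def to_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=np.uint8)
        m[self.index_arrays()] = 1
        return m


@dataclass(frozen=True)
class TargetRegion(Region):
    """Region coupled to the seed, with one CouplingSpec per session."""

    coupling: dict[str, CouplingSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        missing = [s for s in SESSIONS if s not in self.coupling]
        if missing:
            raise ValueError(f"target {self.name!r} missing coupling for sessions {missing}")


@dataclass(frozen=True)
class ClinicalModel:
    """Links percent clinical change to the planted coupling change.

    ``percent_change(HDRS) = hdrs_change_mean + slope * (delta_i - delta_spec)
    + N(0, residual_sd)`` where ``delta_i`` is subject *i*'s realized coupling
    change (spec-level change plus N(0, coupling_change_sd) jitter) and
    ``delta_spec`` the spec-level change; SHAPS uses the negated slope so it
    increases with improvement.  Pre-treatment score means/SDs follow the
    cohort this emulates (HDRS 19 (4.76), SHAPS 32.35 (6.79)).
    """

    hdrs_pre_mean: float = 19.0
    hdrs_pre_sd: float = 4.76
    shaps_pre_mean: float = 32.35
    shaps_pre_sd: float = 6.79
    slope: float = -150.0
    residual_sd: float = 10.0
    coupling_change_sd: float = 0.08
    hdrs_change_mean: float = -55.8
    shaps_change_mean: float = 23.5

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.coupling_change_sd < 0:
            raise ValueError("residual_sd and coupling_change_sd must be >= 0")


@dataclass(frozen=True)
class AgeModel:
    """Normal age distribution truncated to [lo, hi] years."""

    mean: float = 40.7
    sd: float = 11.3
    lo: float = 18.0
    hi: float = 70.0


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 58
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    n_timepoints: int = 604
    tr_seconds: float = 0.8
    voxel_size_mm: float = 2.0
    seed_regions: tuple[Region, ...] = ()
    target_regions: tuple[TargetRegion, ...] = ()
    noise_region: Region | None = None
    noise_sd: float = 1.0
    band: BandSpec = field(default_factory=BandSpec)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    age_model: AgeModel = field(default_factory=AgeModel)
    sex_ratio: float = 28 / 58
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 4 for d in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 dims, each >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.seed_regions:
            raise ValueError("at least one seed region is required")
        seen: set[tuple[int, int, int]] = set()
        for region in self.all_regions():
            overlap = seen & set(region.voxels)
            if overlap:
                raise ValueError(
                    f"region {region.name!r} overlaps another region at voxels {sorted(overlap)[:5]}"
                )
            seen.update(region.voxels)
            for v in region.voxels:
                if any(c < 0 or c >= d for c, d in zip(v, self.grid_shape)):
                    raise ValueError(f"voxel {v} of region {region.name!r} outside grid")

    def all_regions(self) -> list[Region]:
        regions: list[Region] = list(self.seed_regions) + list(self.target_regions)
        if self.noise_region is not None:
            regions.append(self.noise_region)
        return regions

    def validate_for_window(self, longest_window_trs: int) -> None:
        if self.n_timepoints < longest_window_trs:
            raise ValueError(
                f"n_timepoints={self.n_timepoints} shorter than the longest "
                f"analysis window ({longest_window_trs} TRs)"
            )


@dataclass
class TimeSeriesImage:
    """4-D (x, y, z, t) signal array with TR metadata."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("TimeSeriesImage data must be 4-D")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class RoiMask:
    """Named 3-D binary mask."""

    name: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError("RoiMask data must be 3-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask values must be 0/1")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class Cohort:
    spec: CohortSpec
    images: list[tuple[TimeSeriesImage, TimeSeriesImage]]  # (pre, post) per subject
    masks: dict[str, RoiMask]
    table: pd.DataFrame


def default_cohort_spec(**overrides) -> CohortSpec:
    """A compact study-like spec: one seed block, a stationary-coupled and a
    modulation-coupled target block, and a corner noise region for CompCor."""
    def block(x0, y0, z0, nx=2, ny=2, nz=2):
        return tuple(
            (x0 + i, y0 + j, z0 + k)
            for i in range(nx) for j in range(ny) for k in range(nz)
        )

    seed = Region("seed", block(1, 1, 1))
    stationary = TargetRegion(
        "stationary_target",
        block(5, 5, 3, 3, 3, 3),
        coupling={
            "pre": CouplingSpec(static_r=0.4),
            "post": CouplingSpec(static_r=0.55),
        },
    )
    modulated = TargetRegion(
        "modulated_target",
        block(9, 1, 1, 2, 2, 2),
        coupling={
            "pre": CouplingSpec(static_r=0.3, mod_amplitude=0.0),
            "post": CouplingSpec(static_r=0.3, mod_amplitude=0.4),
        },
    )
    noise = Region("noise_roi", block(1, 9, 5, 2, 2, 2))
    base = dict(
        seed_regions=(seed,),
        target_regions=(stationary, modulated),
        noise_region=noise,
    )
    base.update(overrides)
    return CohortSpec(**base)


def _subject_rng(spec: CohortSpec, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed), int(subject_index), int(stream)])


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...], tr: float,
                band: BandSpec) -> np.ndarray:
    """Standardized band-limited Gaussian noise, time along the last axis."""
    x = rng.standard_normal(shape)
    x = bandpass(x, tr, band, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def subject_couplings(spec: CohortSpec, subject_index: int
                      ) -> tuple[dict[str, dict[str, CouplingSpec]], float]:
    """Realized per-subject couplings and the planted coupling change.

    The post-session static coupling of each target gets subject-level jitter
    (SD ``clinical_model.coupling_change_sd``) on its pre-to-post change,
    clipped to keep the coupling admissible; the planted change is the mean
    realized change over target regions.
    """
    rng = _subject_rng(spec, subject_index, _STREAM_COUPLING)
    jitter_sd = spec.clinical_model.coupling_change_sd
    realized: dict[str, dict[str, CouplingSpec]] = {}
    deltas = []
    for target in spec.target_regions:
        pre, post = target.coupling["pre"], target.coupling["post"]
        delta = (post.static_r - pre.static_r) + jitter_sd * rng.standard_normal()
        r_post = pre.static_r + delta
        bound = 0.99 - post.mod_amplitude
        r_post = float(np.clip(r_post, -bound, bound))
        realized[target.name] = {"pre": pre, "post": replace(post, static_r=r_post)}
        deltas.append(r_post - pre.static_r)
    planted_change = float(np.mean(deltas)) if deltas else 0.0
    return realized, planted_change


def generate_subject_session(spec: CohortSpec, subject_index: int,
                             session: str) -> TimeSeriesImage:
    """One subject-session 4-D image; bit-identical for identical arguments."""
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}, got {session!r}")
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside cohort of {spec.n_subjects}")
    rng = _subject_rng(spec, subject_index, _SESSION_CODE[session])
    T, tr, band = spec.n_timepoints, spec.tr_seconds, spec.band
    realized, _ = subject_couplings(spec, subject_index)

    s = _band_noise(rng, (T,), tr, band)  # shared seed signal
    data = spec.noise_sd * _band_noise(rng, spec.grid_shape + (T,), tr, band)

    for region in spec.seed_regions:
        ix = region.index_arrays()
        data[ix] = s + data[ix]

    t_sec = np.arange(T) * tr
    for target in spec.target_regions:
        cpl = realized[target.name][session]
        a_t = cpl.static_r + cpl.mod_amplitude * np.sin(
            2.0 * np.pi * t_sec / cpl.mod_period_seconds
        )
        if np.any(np.abs(a_t) >= 1.0):
            raise ValueError(
                f"instantaneous coupling for target {target.name!r} leaves (-1, 1)"
            )
        ix = target.index_arrays()
        eps = _band_noise(rng, (len(target.voxels), T), tr, band)
        data[ix] = a_t * s + np.sqrt(1.0 - a_t**2) * eps

    return TimeSeriesImage(
        data=data, tr_seconds=tr,
        subject_id=f"sub-{subject_index:03d}", session=session,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int | None = None) -> np.ndarray:
    x = rng.normal(mean, sd, size=size if size is not None else 1)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(x, lo, hi)


def _clinical_rows(spec: CohortSpec, subject_index: int,
                   planted_change: float) -> list[dict]:
    cm = spec.clinical_model
    rng = _subject_rng(spec, subject_index, _STREAM_CLINICAL)
    age = float(_truncated_normal(rng, spec.age_model.mean, spec.age_model.sd,
                                  spec.age_model.lo, spec.age_model.hi)[0])
    sex = int(rng.random() < spec.sex_ratio)

    spec_delta = float(np.mean([
        t.coupling["post"].static_r - t.coupling["pre"].static_r
        for t in spec.target_regions
    ])) if spec.target_regions else 0.0
    centered = planted_change - spec_delta

    hdrs_pre = max(1.0, float(rng.normal(cm.hdrs_pre_mean, cm.hdrs_pre_sd)))
    pc_hdrs = cm.hdrs_change_mean + cm.slope * centered + rng.normal(0.0, cm.residual_sd)
    pc_hdrs = max(-100.0, pc_hdrs)
    hdrs_post = hdrs_pre * (1.0 + pc_hdrs / 100.0)

    shaps_pre = max(1.0, float(rng.normal(cm.shaps_pre_mean, cm.shaps_pre_sd)))
    pc_shaps = cm.shaps_change_mean - cm.slope * centered + rng.normal(0.0, cm.residual_sd)
    pc_shaps = max(-100.0, pc_shaps)
    shaps_post = shaps_pre * (1.0 + pc_shaps / 100.0)

    sid = f"sub-{subject_index:03d}"
    common = dict(subject_id=sid, age=round(age, 1), sex=sex,
                  planted_dcoupling=planted_change)
    return [
        {**common, "session": "pre", "hdrs": round(hdrs_pre, 2), "shaps": round(shaps_pre, 2)},
        {**common, "session": "post", "hdrs": round(hdrs_post, 2), "shaps": round(shaps_post, 2)},
    ]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full deterministic cohort: image pairs, masks, and the clinical table."""
    if spec.n_subjects < 3:
        raise ValueError("n_subjects must be >= 3 for downstream statistics")
    images = []
    rows: list[dict] = []
    for i in range(spec.n_subjects):
        pre = generate_subject_session(spec, i, "pre")
        post = generate_subject_session(spec, i, "post")
        images.append((pre, post))
        _, planted = subject_couplings(spec, i)
        rows.extend(_clinical_rows(spec, i, planted))
    masks = {r.name: RoiMask(r.name, r.to_mask(spec.grid_shape))
             for r in spec.all_regions()}
    masks["brain"] = RoiMask("brain", np.ones(spec.grid_shape, dtype=np.uint8))
    table = pd.DataFrame(rows, columns=[
        "subject_id", "session", "age", "sex", "hdrs", "shaps", "planted_dcoupling",
    ])
    logger.info("generated cohort: %d subjects, grid %s, T=%d",
                spec.n_subjects, spec.grid_shape, spec.n_timepoints)
    return Cohort(spec=spec, images=images, masks=masks, table=table)


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def _save_nifti(path: Path, data: np.ndarray, voxel_size_mm: float,
                tr_seconds: float | None = None) -> None:
    img = nib.Nifti1Image(data, _affine(voxel_size_mm))
    if tr_seconds is not None:
        zooms = (voxel_size_mm,) * 3 + (tr_seconds,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: Cohort, directory: str | Path) -> dict:
    """Write images/masks as NIfTI and the clinical table as CSV.

    Returns (and writes as ``manifest.json``) a manifest listing every file
    with its SHA-256 checksum; reading the files back reproduces the arrays
    bit-exactly (images are stored float32, masks uint8).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vs, tr = cohort.spec.voxel_size_mm, cohort.spec.tr_seconds
    files: dict[str, dict] = {}

    for pre, post in cohort.images:
        for img in (pre, post):
            name = f"{img.subject_id}_{img.session}_bold.nii"
            _save_nifti(directory / name, img.data, vs, tr)
            files[name] = {"kind": "image", "subject_id": img.subject_id,
                           "session": img.session}
    for mask in cohort.masks.values():
        name = f"mask_{mask.name}.nii"
        _save_nifti(directory / name, mask.data, vs)
        files[name] = {"kind": "mask", "name": mask.name}
    cohort.table.to_csv(directory / "clinical.csv", index=False)
    files["clinical.csv"] = {"kind": "clinical"}

    for name, meta in files.items():
        meta["sha256"] = _sha256(directory / name)
    manifest = {
        "n_subjects": cohort.spec.n_subjects,
        "tr_seconds": tr,
        "voxel_size_mm": vs,
        "grid_shape": list(cohort.spec.grid_shape),
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote cohort to %s (%d files)", directory, len(files))
    return manifest


def read_cohort(directory: str | Path) -> tuple[list[tuple[TimeSeriesImage, TimeSeriesImage]],
                                                dict[str, RoiMask], pd.DataFrame]:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tr = manifest["tr_seconds"]
    by_subject: dict[str, dict[str, TimeSeriesImage]] = {}
    masks: dict[str, RoiMask] = {}
    for name, meta in manifest["files"].items():
        if meta["kind"] == "image":
            arr = np.asanyarray(nib.load(str(directory / name)).dataobj)
            img = TimeSeriesImage(arr, tr, subject_id=meta["subject_id"],
                                  session=meta["session"])
            by_subject.setdefault(meta["subject_id"], {})[meta["session"]] = img
        elif meta["kind"] == "mask":
            arr = np.asanyarray(nib.load(str(directory / name)).dataobj)
            masks[meta["name"]] = RoiMask(meta["name"], arr)
    table = pd.read_csv(directory / "clinical.csv")
    images = [(by_subject[s]["pre"], by_subject[s]["post"])
              for s in sorted(by_subject)]
    return images, masks, table
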