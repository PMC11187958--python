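import numpy as np
import pytest

from seedfc import (CohortSpec, CouplingSpec, Region, TargetRegion,
                    default_cohort_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def small_spec():
    """Compact cohort spec used across modules: 3 subjects, short series."""
    return default_cohort_spec(n_subjects=3, n_timepoints=160, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    from seedfc import generate_cohort
    return generate_cohort(small_spec)


def modulation_spec(mod_amplitude, rng_seed, static_r=0.3, n_timepoints=300,
                    n_subjects=3):
    """Two targets with equal static coupling; one is amplitude-modulated."""
    def block(x0, y0, z0):
        return tuple((x0 + i, y0 + j, z0 + k)
                     for i in range(2) for j in range(2) for k in range(2))

    cpl_s = {"pre": CouplingSpec(static_r=static_r),
             "post": CouplingSpec(static_r=static_r)}
    cpl_m = {"pre": CouplingSpec(static_r=static_r, mod_amplitude=mod_amplitude),
             "post": CouplingSpec(static_r=static_r, mod_amplitude=mod_amplitude)}
    return CohortSpec(
        n_subjects=n_subjects, n_timepoints=n_timepoints,
        seed_regions=(Region("seed", block(1, 1, 1)),),
        target_regions=(TargetRegion("stationary_target", block(6, 6, 3),
                                     coupling=cpl_s),
                        TargetRegion("modulated_target", block(9, 1, 1),
                                     coupling=cpl_m)),
        noise_region=Region("noise_roi", block(1, 9, 5)),
        rng_seed=rng_seed)


def region_mean_dfcv(spec, subjects, session="pre", window_trs=84):
    """Per-region dFCv averaged over target voxels and the given subjects."""
    import numpy as np
    from seedfc import RoiMask, SeedSeries, WindowSpec, dfcv_map, \
        generate_subject_session
    brain = RoiMask("brain", np.ones(spec.grid_shape, dtype=np.uint8))
    seed_vox = spec.seed_regions[0].to_mask(spec.grid_shape).astype(bool)
    sums = {t.name: [] for t in spec.target_regions}
    for s in subjects:
        img = generate_subject_session(spec, s, session)
        seed = SeedSeries("seed", img.data[seed_vox].mean(axis=0))
        out = dfcv_map(seed, img, brain, WindowSpec(window_trs))
        for t in spec.target_regions:
            sums[t.name].append(np.mean([out.data[v] for v in t.voxels]))
    return {name: float(np.mean(v)) for name, v in sums.items()}


def spec_with_couplings(pre_stationary, post_stationary, pre_mod=0.0,
                        post_mod=0.0, **overrides):
    """Spec with a single target region and explicit per-session coupling."""
    seed = Region("seed", tuple((1 + i, 1 + j, 1 + k)
                                for i in range(2) for j in range(2) for k in range(2)))
    target = TargetRegion(
        "target",
        tuple((6 + i, 6 + j, 3 + k)
              for i in range(2) for j in range(2) for k in range(2)),
        coupling={
            "pre": CouplingSpec(static_r=pre_stationary, mod_amplitude=pre_mod),
            "post": CouplingSpec(static_r=post_stationary, mod_amplitude=post_mod),
        },
    )
    noise = Region("noise_roi", tuple((1 + i, 9 + j, 5 + k)
                                      for i in range(2) for j in range(2) for k in range(2)))
    defaults = dict(n_subjects=3, n_timepoints=300, seed_regions=(seed,),
                    target_regions=(target,), noise_region=noise)
    defaults.update(overrides)
    return CohortSpec(**defaults)
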