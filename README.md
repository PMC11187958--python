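# seedfc

Seed-based static and dynamic functional-connectivity analysis for
resting-state fMRI, with permutation inference — built to study how
treatment (e.g. serial ketamine infusions in depression) changes the
coupling between small subcortical seeds such as the habenula (Hb) and
nucleus accumbens (NAc) and the rest of the brain, and whether those
changes track clinical improvement.

The package covers the full chain for two-session (pre/post) cohorts:

1. **Denoising** — CompCor-style nuisance regression (principal components
   of a noise-region's time series) plus a zero-phase band-pass filter to
   the resting-state band [0.015, 0.1] Hz, applied as one linear projection
   per voxel series.
2. **Seed extraction** — mask-average time series per seed, optionally
   cleaned by regressing out signals from small spheres in adjacent
   structures (partial-volume decontamination).
3. **Connectivity maps** — per seed, subject, and session:
   * static FC (sFC): Fisher-z of the full-length Pearson correlation,
     `z = atanh(r)`, seed vs. every brain voxel;
   * dynamic FC variability (dFCv): a Hamming-tapered window of W = 84 TRs
     (67 s at TR = 0.8 s) slides in steps of 1 TR; within each window a
     taper-weighted correlation is Fisher-z transformed, and the sample
     standard deviation (N−1) of the windowed z values is the voxel's dFCv.
     Window-length sensitivity maps (63 and 125 TRs) are one call away.
4. **Group inference** — voxelwise OLS t statistics on post-minus-pre
   change maps (age and sex as covariates of no interest), enhanced with
   threshold-free cluster enhancement,

   `TFCE(v) = Σ_h e_v(h)^E · h^H · dh`  (E = 0.5, H = 2, dh = max/100),

   and corrected for family-wise error with the permutation distribution of
   the maximum TFCE statistic (Freedman–Lane scheme: sign-flips for the
   paired test, subject permutations for the clinical-change correlations;
   5000 permutations by default). Clinical percent-change vectors are
   screened for ±3 SD outliers first. Scalar statistics (paired and
   two-sample t, Pearson χ², partial correlations controlling for age/sex,
   remission classification at HDRS ≤ 7) round out the cohort description.
5. **Synthetic cohorts** — a deterministic generator that plants known
   static and sinusoidally amplitude-modulated seed–target coupling
   (variance-preserving mixing `y_t = a_t·s_t + √(1−a_t²)·ε_t`) and links
   percent change in HDRS/SHAPS scores to each subject's planted coupling
   change, so every stage can be validated against ground truth.

## Worked example

Simulate a 58-subject two-session cohort with planted effects and analyze
it (the `seedfc` console script wraps the `seedfc.pipeline` module):

```bash
cat > study.yaml <<EOF
n_subjects: 58
n_timepoints: 604
n_perm: 500
seed: 7
data_dir: cohort58
out_dir: results58
EOF
seedfc --mode simulate --config study.yaml
seedfc --mode analyze  --config study.yaml
head -6 results58/cluster_summary.tsv
```

```
analysis	cluster	n_voxels	peak_t	peak_p_fwer	peak_i	peak_j	peak_k	peak_x_mm	peak_y_mm	peak_z_mm
seed_sfc_paired	1	27	9.88074	0.001996	7	7	5	14	14	10
seed_sfc_corr_hdrs	1	1	-4.36608	0.01996	9	1	2	18	2	4
seed_sfc_corr_shaps	1	13	4.93222	0.001996	5	5	3	10	10	6
seed_dfcv_paired	1	5	6.84938	0.001996	10	2	2	20	4	4
```

Each row is a cluster of voxels with FWER-corrected p < 0.05. The default
synthetic cohort plants (a) a pre-to-post increase in static coupling in a
27-voxel "stationary target" block and (b) a pre-to-post increase in
coupling *modulation* (amplitude 0 → 0.4) in a second block — and the
analysis recovers exactly that: the paired sFC test finds the full
stationary block (peak voxel (7,7,5), p = 1/501 ≈ 0.002, the smallest
attainable p at 500 permutations), the paired dFCv test finds the modulated
block, and the clinical correlations attach to the planted regions with the
planted signs (HDRS improvement is encoded as negative percent change, so
its slope is negative; SHAPS rises with improvement, so its slope is
positive). Every map (`*_tstat.nii`, `*_tfce.nii`, `*_pfwer.nii`) is also
written as NIfTI, and `run_log.json` records every parameter and seed so a
run can be reproduced exactly.

## Layout

| module | contents |
| --- | --- |
| `seedfc.synthetic` | cohort spec, planted-coupling generator, NIfTI/CSV I/O |
| `seedfc.denoise` | band-pass filter, CompCor components, nuisance regression |
| `seedfc.seeds` | ROI averaging, sphere masks, seed decontamination |
| `seedfc.connectivity` | weighted correlation, Fisher z, sFC and dFCv maps |
| `seedfc.inference` | TFCE, permutation tests, FWER p-values, scalar statistics |
| `seedfc.pipeline` / `seedfc.cli` | configuration, orchestration, reporting |

See `docs/methods.md` for the statistical model, parameter choices, and
known limitations.
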