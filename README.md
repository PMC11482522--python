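# petmcc — dynamic PET/CT quantification of mucociliary clearance

Mucociliary clearance (MCC) — the transport of mucus and anything embedded
in it out of the airways by ciliary beating — is a primary airway defense
and is impaired in diseases such as cystic fibrosis. `petmcc` quantifies
MCC from dynamic PET/CT: a radiolabelled particle tracer (e.g. [68Ga]-MAA,
half-life 68 min) is deposited in the distal airways, imaged in 10-s
frames, and the decay-corrected loss of tracer from anatomically defined
regions of interest gives a **%Cleared** curve per subject.

The package is aimed at imaging scientists who need a reproducible,
scriptable version of this analysis, and provides:

- **volume I/O** — NIfTI volumes and 4-D series, list-mode event binning
  into fixed frames (`petmcc.volume`);
- **segmentation** — region-growing HU thresholding (airway < −700,
  parenchyma < −200), morphological closing, and the peripheral
  **hollow-shell ROI** (default 1.5 mm) defined via an exact Euclidean
  distance transform, plus the micro-CT shell-depth analysis for small
  (< 200 µm) airways (`petmcc.segmentation`);
- **centerline analysis** — 3-D skeletonization of the airway, cubic-spline
  centerline, extrapolation to the pleura, perpendicular-disk profiles and
  the distal 2-mm cylinder ROI (`petmcc.centerline`);
- **clearance kinetics** — time–activity curves, Ga-68 decay correction,
  %Cleared, two-phase exponential fits, extra sum-of-squares F tests,
  responder classification with Fisher's exact test (`petmcc.clearance`);
- **a synthetic phantom** — dichotomous airway trees in an ellipsoidal
  lung, HU-class CT, two-phase tracer kinetics, PSF blur and Poisson
  counting, with full ground-truth manifests (`petmcc.phantom`);
- **a pipeline + CLI** — `petmcc simulate | run | stats`
  (`petmcc.pipeline`, `petmcc.cli`).

## The model

%Cleared is modelled as a two-phase exponential association with three
parameters, starting at 0 and plateauing at 100 %:

    pct(t) = 100 · (1 − f·e^(−k_fast·t) − (1 − f)·e^(−k_slow·t)),
    0 ≤ f ≤ 1,  k_fast ≥ k_slow ≥ 0  [min⁻¹]

Groups are compared by the extra sum-of-squares F test between one pooled
fit and per-group fits, and by Fisher's exact test on responder counts
(subjects clearing strictly more than 20 % by 12 min). See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a two-group phantom cohort (a fast-clearing "non-CF-like" group
and a slow "CF-like" group, 3 subjects each) and run the shell analysis:

```sh
cat > sim.yaml <<'YAML'
shape: [72, 72, 72]
spacing_mm: [1.0, 1.0, 1.0]
lung_semi_axes_mm: [24.0, 28.0, 32.0]
body_margin_mm: 4.0
n_per_group: 3
seed: 7
subject_jitter_sigma: 0.1
tree: {root_radius_mm: 2.0, root_length_mm: 16.0, length_ratio: 0.8}
group_kinetics:
  non_cf_like: {f: 0.15, k_fast: 0.8, k_slow: 0.011}
  cf_like:     {f: 0.08, k_fast: 0.6, k_slow: 0.006}
YAML
petmcc simulate --config sim.yaml --out data
cat > run.yaml <<'YAML'
data_dir: data
out_dir: results
scheme: shell
YAML
petmcc run --config run.yaml
```

prints

```
wrote 6 phantom subjects to data
[shell] cf_like: %Cleared(12 min) = 13.5 ± 0.3% (n=3)
[shell] non_cf_like: %Cleared(12 min) = 25.7 ± 1.6% (n=3)
[shell] F(3,534) = 2082.16, p = 3.59e-294
report written to results/report.json
```

Reading this: by the end of the 12-min acquisition the fast group cleared
25.7 % of its deposited dose (mean ± SE over subjects) from the peripheral
1.5-mm shell versus 13.5 % for the slow group, and the F test overwhelmingly
rejects the hypothesis that one clearance curve explains both groups
(3 extra parameters, 534 residual degrees of freedom). `results/report.json`
additionally holds the per-group two-phase parameters, responder
contingency tables with Fisher p-values, and per-subject curves
(`results/curves.csv`).

The same pipeline runs on real data: point `data_dir` at subject folders
containing `ct.nii.gz` and `pet_4d.nii.gz` (with a `pet_4d.frametimes.json`
sidecar) and a `manifest.json` listing subjects, groups and an airway seed
voxel per subject.

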