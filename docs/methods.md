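# Methods

## Problem and model

`brainprint` treats a spatially normalized gray-matter (GM) probability map
as a biometric signature. After tissue segmentation and nonrigid
registration into a common template space, every brain occupies the same
voxel grid, so two brains can be compared voxel by voxel with no feature
extraction — normalized brains lack the stable point features (minutiae-like
landmarks) that feature-based matchers rely on.

Let G_a(x), G_b(x) be two aligned GM maps, x ranging over all voxel
coordinates. The dissimilarity is the L1 voxel distance

    d(a, b) = Σ_x | G_a(x) − G_b(x) |,

optionally Σ_x (G_a(x) − G_b(x))² (`metric="l2"`). A smaller d means a
higher chance that the two scans show the same brain. All distances of one
experiment (genuine and imposter pooled) are min–max normalized to matching
scores on [0, 100]:

    s = 100 · (d_max − d) / (d_max − d_min),

so the pool's best match scores exactly 100 and its worst exactly 0. The
evaluation pipeline is invariant under any monotone transform of d, so the
choice between L1 and L2 changes score values but not separability, ROC
shape, or rank-1 decisions in any qualitative way; L1 is the default and the
form used in every shipped experiment.

Scores are consumed by the two standard biometric protocols:

- **Verification (1-to-1).** Genuine pairs are two scans of one subject —
  either from the same imaging session (`same_visit`) or from sessions
  separated in time (`different_visit`, which adds intra-class variability).
  Imposter pairs take one volume per subject (default: second scan of the
  first visit) and form all C(N, 2) cross-subject pairs — 11,175 for N=150.
  At threshold t, FRR is the percentage of genuine pairs with s < t and FAR
  the percentage of imposter pairs with s > t; the inequalities are strict,
  so a score equal to t counts as accepted-genuine and correctly-rejected-
  imposter. The ROC sweeps t over all observed scores, the midpoints
  between consecutive observed scores (both rates are step functions that
  change *at* observed scores, so equal-error plateaus may sit strictly
  between two of them), and one point beyond each extreme. The EER is the
  swept point with FAR = FRR when one exists (smallest threshold on ties,
  flagged `exact_crossing`); otherwise the crossing of the piecewise-linear
  interpolants of FAR(t) and FRR(t) between the two adjacent sweep points
  where FAR − FRR changes sign. The separation gap (max imposter score,
  min genuine score) certifies EER = 0 whenever the former is strictly
  below the latter.

- **Closed-set identification (1-to-N).** A gallery enrolls one volume per
  subject (default selector: visit 1, scan 2). For each probe (default:
  visit 2, scan 2) the distances to all gallery entries are computed and
  normalized over that probe's pool; the arg-max-score subject is returned.
  Since min–max normalization is monotone, the per-probe pooling cannot
  change the arg-max; the returned score of the winner is 100 by
  construction. Exact distance ties (measure-zero on real data, possible on
  synthetic fixtures) return the lexicographically smallest subject id and
  set a `tie` flag. The identification ratio is the percentage of probes
  whose true subject is returned at rank 1.

### Pair-count combinatorics

For a subject with V visits and m_j scans at visit j, the package uses the
general forms Σ_{j<k} m_j·m_k (`different_visit`) and Σ_j C(m_j, 2)
(`same_visit`); the former reduces to C(V, 2)·m² when every visit has m
scans. The dataset total is the sum over subjects, and a property test
checks the closed forms against brute-force enumeration on random visit
structures.

## Preprocessing in scope

The package consumes GM maps that are already segmented and normalized;
registration itself is out of scope. The one preprocessing step it owns is
the final isotropic Gaussian smoothing, with σ_vox = FWHM / (voxel_size ·
2√(2 ln 2)) per axis and kernels truncated at 4σ. The FWHM is a
configuration parameter, default 8 mm (the usual choice for VBM-style GM
analyses); smoothing outputs are clipped back to [0, 1]. Volumes are
validated on ingest: values must lie in [0, 1] up to a 1e−6 tolerance
(clipped) — anything further is rejected as not a probability map — and all
volumes of one experiment must share grid shape and voxel size.

## Synthetic phantom generator

Real longitudinal cohorts cannot ship with the package, so every stage is
exercised on synthetic phantoms that reproduce the *statistical structure*
the method assumes, not brain anatomy:

    scan(s, v, k) = clip( base
                        + subject_amplitude · field_s
                        + visit_drift_sd    · field_{s,v}
                        + scan_noise_sd     · white_{s,v,k} , 0, 1)

- `base`: a shared ellipsoidal cortical shell (GM ≈ 0.8 between 55% and 95%
  of the ellipsoid radius, 0 elsewhere) standing in for the population-mean
  GM pattern after normalization.
- `field_s`: the subject's stable, unique anatomy — white Gaussian noise
  smoothed to a correlation length of `smoothness_vox` voxels (default 2)
  and standardized to unit sd over the shell, so differences are spatially
  coherent rather than salt-and-pepper.
- `field_{s,v}`: a per-visit smooth drift field, identical for all scans of
  one session — the intra-class variability between sessions (repositioning,
  scanner state, slow anatomical change).
- `white_{s,v,k}`: per-scan voxelwise acquisition noise.

Seeding is hierarchical — (master_seed, tag, subject[, visit[, scan]])
through numpy `SeedSequence` — so any single volume is reproducible in
isolation and the three noise layers draw from disjoint streams.

Defaults: 150 subjects × 2 visits × 3 scans on a 32³ grid of 2 mm voxels,
`subject_amplitude` 0.2, `visit_drift_sd` 0.05, `scan_noise_sd` 0.02. The
amplitude hierarchy (subject ≫ drift > noise) puts the default cohort in the
fully separable regime — Same-Visit EER 0.0% with a clear score gap and a
100% rank-1 identification ratio — which is the qualitative regime reported
for real normalized GM data; the drift and noise magnitudes are chosen for
that regime, not calibrated to any real cohort's statistics. What passing
tests show is therefore that the *pipeline* behaves correctly under the
assumed statistical structure; they say nothing about segmentation or
registration quality on real MRI, about pathology or ageing effects, or
about the absolute scale of real intra-class variability.

## Numerical choices

- Distances accumulate in float64; volume payloads are float32 (exact NIfTI
  round-trip).
- Score normalization computes (d_max − d)/span before scaling by 100 so the
  extremes map to exactly 100.0 and 0.0 in floating point. A pool whose
  distances are all equal maps everything to 100 (each pair is the pool's
  best match).
- Score CSVs are written with `%.17g` so every number in the JSON summary is
  bit-recomputable from the CSVs (read with `float_precision="round_trip"`).
- `generate_dataset` writes uncompressed `.nii` so reruns are byte-identical
  (gzip embeds timestamps).
- Degenerate inputs fail loudly: empty pair lists and empty score pools
  raise, as do missing selector scans, sub-2-subject galleries, grid
  mismatches and out-of-range probability values.

## Problem sizes used in the shipped experiments

The headline experiments (acceptance script, and the corresponding tests)
run the full default cohort: 900 volumes on a 32³ grid, 900 Same-Visit
genuine pairs + 11,175 imposter pairs, and 150 gallery/probe pairs.
Statistical property checks (chance-level identification, degradation with
drift, distance monotonicity) use smaller cohorts (5–8 subjects, 16³ grids)
averaged over 10–20 seeds.

## Known limitations

- Phantoms are Gaussian-field caricatures: no gyral anatomy, no MR physics,
  no motion artifacts, no systematic ageing drift direction.
- The EER of a finite score set is quantized at 100/n percentage points;
  the interpolated estimator can differ from a fine-grid threshold search by
  up to half that quantum on small pools.
- Closed-set only: every probe's subject is assumed enrolled; there is no
  reject option or open-set evaluation, and no CMC beyond rank 1.
- Min–max score normalization is pool-relative; scores are not comparable
  across experiments, and the normalization is sensitive to a single
  outlier pair (it only shifts/scales, never reorders).
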