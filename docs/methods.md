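# Methods

This note documents the models, algorithms and numerical choices behind
`breathdisc`, and what the synthetic cohorts do and do not establish about
real breath data.

## Signal model of the synthetic cohorts

A subject's chromatogram is a scan-time × m/z matrix

    I(s, m) = d · [ b(s)/C + Σ_c A_c · N(s; apex_c + δ_c, σ_c) · S_c(m) ] · (1 + ε·cv)₊

with `d` the subject's dilution factor (log-normal, `dilution_sd`), `b` a
smooth drift (sum of three low-frequency sines with random phases, amplitude
`baseline_amp` relative to the median peak apex, spread over the `C`
channels), `N` a unit-area Gaussian in retention time so the TIC area of a
compound equals its abundance, `δ_c` per-compound retention jitter
(`rt_jitter_sd` scans), `S_c` a unit-sum mass spectrum with 5–15 integer m/z
lines (Dirichlet weights; lines are drawn from a shared pool with
probability 0.2 so distinct compounds can share fragments), and `ε` standard
normal — multiplicative, hence heteroscedastic, noise clipped so intensities
stay non-negative. Acquisition geometry defaults to the instrument's
m/z 35–350 at 5 scans/s; the run length is scaled to 11 min (3300 scans) for
tractable simulation sizes, with `SimulationConfig.full_scale()` restoring
the 33-min, 9900-scan geometry.

Abundances are log-normal: `log A = base_c + group shift + subject effect`,
with a between-subject SD of 0.5 (log scale). A compound discriminating a
contrast shifts its group means by ±`effect_size`/2 between-subject SDs
(sign random per compound; contrast sets may overlap). Compound apexes sit
on a jittered grid with widths capped at an eighth of the grid spacing:
sparse catalogs (≈50 compounds at 3300 scans) are then baseline-resolved —
a prerequisite for exact feature-count recovery — while dense catalogs
(200+) overlap like real chromatograms.

A latent severity score `z ~ N(0,1)` per subject drives both the
disease-contrast (A↔B) compounds and the designated clinical columns
(default TLC and 6MWD analogues) with correlation `clinical_coupling`
(default 0.7). The latent structure is applied to *every* subject —
controls carry their own draw — so that an `effect_size=0` cohort is a true
null for the discriminant layer: otherwise the patients-only correlation
structure is itself a class signature. Severity is an impairment score with
positive loading on the coupled columns (the invariant tested is
corr(z, column) = ρ); clinically TLC falls with worse disease, so the sign
convention is a simulator convenience, not a physiological claim. Clinical
tables reproduce the study table's shape: age/sex/smoking distributions per
group, lung-function columns as percent predicted, controls carrying NA
there. Age, sex and smoking are generated independently of the VOCs, so the
confounder tests operate under a known null.

Determinism: all draws derive from `(config, seed)`; per-run render streams
are spawned as `SeedSequence((seed, salt, sample_index))`, so a cohort is
bit-identical across calls and platforms.

What the simulator does *not* model: co-eluting isomers with near-identical
spectra, detector saturation, column bleed with structured m/z signatures,
batch effects across measurement days, missing scans. Passing tests
therefore demonstrate internal correctness of the pipeline and calibration
of its statistics under the stated noise model — not performance on real
breath data.

## Preprocessing

Stages run in a fixed, stage-tagged order; applying one out of order raises.

* **Log transform** ln(1+x) (exact zeros are legal) converts the
  multiplicative noise into approximately additive noise so that a single
  threshold per channel is meaningful downstream.
* **Wavelet denoising**: db4, 2 decomposition levels, soft threshold
  σ̂·√(2 ln n) per channel with σ̂ = MAD(finest details)/0.6745. Wavelet
  order and level count are config-exposed.
* **Baseline**: asymmetric least squares — iteratively reweighted
  second-difference-penalized smoothing (λ = 1e5, p = 0.001, 10 iterations),
  solved with a symmetric pentadiagonal banded solver. The curve is
  *estimated* on the log trace, where the asymmetric weighting is robust,
  but *subtracted* on the raw intensity scale: drift adds to ion counts, and
  subtracting its log would divide the peaks by (1 + baseline), entangling
  dilution with baseline. Channels whose valley floor (25th percentile)
  stays below 1% of the channel maximum are left untouched — there the
  fitted "baseline" is indistinguishable from zero and subtracting its
  ripple would only distort peak areas.
* **Alignment**: the cohort-median TIC is the reference; each run's TIC is
  segmented (100 scans), the integer shift (±25) maximizing Pearson
  correlation found per segment, and shifts interpolated linearly between
  segment centers. Guards added after adversarial testing: a shift must buy
  a minimum correlation gain (0.03) over the unshifted match and land on a
  decent match (r ≥ 0.5) — amplitude differences between runs otherwise
  produce spurious 1–2-scan warps; ambiguous segments are excluded from the
  interpolation; a 3-point median filter removes lone outlier segments;
  boundary windows are cropped to their overlap. Shifts saturating the cap
  are reported — larger misalignments are not recoverable.
* **PQN**: dilution is multiplicative in raw intensities, so quotients are
  computed and applied on the back-transformed (expm1) scale. Reference =
  median raw TIC across runs; quotient scans must exceed both the 25th
  percentile and 1% of the reference maximum (baseline-residual valleys
  carry no dilution information and would contaminate the median). The
  per-run median quotients are returned as dilution estimates.
* **Peak picking**: on the cohort-mean raw-scale TIC, local maxima with
  prominence ≥ 5σ̂ (σ̂ from the MAD of the first-differenced trace) become
  peaks; bounds at flanking minima; per-sample areas are trapezoidal
  integrals of that sample's raw TIC over the shared bounds, so the output
  matrix is rectangular by construction. Areas are reported in raw
  intensity units — the log scale is a denoising device, not a
  quantification scale.
* **Peak merging**: peaks whose consensus spectra correlate ≥ 0.95 with
  apexes within 15 scans merge greedily in descending correlation order
  (union-find; ties to the earlier apex); merged area = sum, merged
  spectrum = area-weighted mean.

## Discrimination

* **Duplex split** (per class, on z-scored features, Euclidean distance):
  the two mutually farthest points seed the training set, the next farthest
  pair seeds the test set, and farthest remaining pairs alternate between
  the sets until the test quota — round-half-up of 20% per class — is
  reached; the remainder trains. Fully deterministic, ties to the smaller
  index. Pair alternation (Snee's original scheme) matters: assigning
  single max-min-distance points instead yields an interpolative test set
  whose null test AUC centers near 0.55 rather than 0.5 (measured over 150
  null replicates).
* **Forest**: sklearn `RandomForestClassifier` (default 500 trees in the
  workflow functions, mtry = ⌊√p⌋, seed mandatory) wrapped as
  `ProximityForestClassifier`, which adds what sklearn does not expose:
  per-tree OOB permutation importance (mean decrease in OOB accuracy when a
  feature's OOB values are permuted; trees not using the feature contribute
  zero) and proximity matrices. Proximities between the model's own samples
  count co-landings only over trees where *both* samples are out of bag:
  in-bag co-landing encodes the fitted labels and fabricates class
  structure even under a label-free null (measured silhouette ≈ 0.32 under
  label shuffling with all-tree proximities, ≈ 0 with OOB proximities).
  Out-of-model samples use all trees.
* **VOC selection**: sort importances descending; within the top 50,
  eligible cut points are gaps whose lower side is already in the noise
  floor (below 10% of the top importance); the largest eligible gap wins if
  it exceeds twice the median gap, else a fixed-count fallback fires with a
  warning. The floor condition is essential: the raw largest gap is almost
  always the one right after the single best feature.
* **Validation**: refit on the selected VOCs, report test
  accuracy/sensitivity/specificity at vote threshold 0.5 (positive class =
  the disease, or the first class for disease–disease pairs), the ROC over
  all vote thresholds, and the AUC as the tie-aware Mann–Whitney statistic.
  OOB-side metrics are reported alongside, since published reports are often
  ambiguous about which set their headline numbers use.
* **Embedding**: classical scaling of D = 1 − proximity (double-centered
  −½JD²J, eigendecomposition; negative eigenvalues truncated at 0 with a
  logged count). Out-of-sample projection by the Gower extension
  score_k = −½(d² − rowmean(D²))ᵀ v_k / √λ_k; exact members of the embedded
  set return their stored row, so the extension agrees exactly on the
  model's samples.

## Fusion

Each sample receives its first k = 2 proximity-PCA coordinates from each of
the three binary models (own score when in the model, Gower projection
otherwise); the 6-dimensional concatenation is reduced to 3-D by PCA for
visualization, and the group silhouette in that view summarizes three-group
separation. The construction of the combined score space (components per
model, final reduction) is an interpretation of "hierarchical model fusion";
k and the view dimension are configurable.

## Inference statistics

* **Ridge CCA**: both blocks are ln(1+x)-transformed (negative-valued
  columns are shifted to start at 0 first) and column-standardized; the
  first canonical pair comes from Cholesky-whitened SVD of the
  cross-covariance with ridge 1e-3 added to both within-block covariances.
  ρ₁ is reported as the (sign-fixed, clipped) correlation of the unit-
  variance canonical variates. Significance is by permutation of the
  clinical block's rows, p = (1 + #{ρ ≥ ρ_obs})/(B + 1), because the
  maximized statistic has a strongly non-null distribution even for
  independent blocks.
* **Clinical subset selection**: greedy forward selection over the eight
  lung-function columns. Each candidate is scored by ρ₁ of the augmented
  model minus its *conditional*-permutation mean — only the candidate
  column's rows are permuted while accepted columns stay intact, so the
  penalty is exactly the overfit a useless extra column would buy. The best
  candidate is admitted if its conditional-permutation p-value clears a
  per-step Bonferroni-corrected α (0.05 / remaining candidates). A
  full-block permutation penalty was tried first and rejected: its penalty
  grows faster than the true gain of a second genuinely coupled column, so
  it systematically returns one column where two are planted.
* **Regularized MANOVA**: statistic det(W + γI)/det(T + γI) with W/T the
  within/total scatter and γ from a Ledoit–Wolf shrinkage rule on the
  pooled within-group residuals — usable when VOCs outnumber samples.
  Continuous factors are dichotomized at the median (logged); p-values by
  permutation of the factor. Validated by type-I calibration (0.05 ± 0.03
  over 200 null replicates) and by Spearman agreement with Hotelling's T²
  ordering on low-dimensional instances, rather than by numeric identity to
  any particular published variant.
* **Univariate battery**: Welch t-tests (a pooled-variance switch exists),
  Benjamini–Hochberg FDR across the battery, Lilliefors normality flags via
  statsmodels (whose critical values follow the standard approximation; the
  test's 5% level is verified by Monte Carlo in the test suite).
  Zero-variance variables are flagged and excluded from the FDR battery.

## Problem sizes and tolerances

Simulation-heavy checks run at deliberately scaled sizes: recovery checks on
30-subject cohorts (50 compounds noiseless / 200 with noise), null
calibration on 20 effect-0 cohorts of 40 per group with two forest-seed
replicates per model (the single test AUC has sd ≈ 0.15 at 16 held-out
samples, so replication is needed before a ±0.05 band on the mean is a fair
check), signal recovery on 20 cohorts of 50/50 with 10 planted VOCs at 1.5
SD, and CCA recovery on 20 cohorts of 80 patients. Permutation tests use
B = 99–999 in batteries and B = 999+ for single reported p-values.

## Known limitations

* Alignment recovers rigid or slowly varying shifts up to ±25 scans; it
  cannot fix per-compound jitter or shifts beyond the cap (it warns).
* The importance-gap cut, like any automatic surrogate for a cut "drawn by
  eye", admits a few noise features riding the gap at realistic effect
  sizes; counts of selected VOCs should be read with that in mind.
* Duplex validation sets are deterministic and spread-based, not random;
  their test metrics are not interchangeable with cross-validation
  estimates.
* The merge step assumes split peaks of one compound have near-identical
  spectra; co-eluting isomers with near-identical spectra would merge
  incorrectly (and are not simulated).
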