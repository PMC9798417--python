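# Methods

This note records the statistical models, numerical conventions, and design
choices behind `metafinger`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing model

**Scan averaging.** An ambient-MS acquisition yields several continuous
centroided scans per sample (10 by default). Peaks pooled over the scans are
clustered by the same mass rule used for binning; each cluster becomes one
averaged peak with intensity = cluster total / number of scans, so a peak
absent from a scan counts as zero there. The averaged m/z is the
intensity-weighted centroid.

**Mass bins.** A bin is a group of observed m/z values within a ±0.005 Da
tolerance. Bins are constructed globally: all m/z values from all samples are
sorted and split wherever the gap between neighbours exceeds twice the
tolerance (single linkage with a gap rule). This construction is
deterministic and independent of sample order — shuffling samples permutes
matrix rows only — at the cost of allowing a chain of close peaks to form a
bin wider than one nominal window. For fingerprints whose ions are separated
by much more than the tolerance (as in the synthetic cohorts) the two
constructions coincide.

**Normalization and scaling.** TIC normalization divides each sample row by
its *mean* peak intensity (the "average total ion current"; a sum-based
variant is available via `use_sum=True`). Scaling is ln(x + ε) followed by
per-bin centering and division by the n−1 standard deviation; ε defaults to
half the smallest nonzero matrix value so zeros stay defined, and constant
bins map to all-zero columns rather than dividing by zero. The n−1 convention
is used consistently (a two-sample column with values v and v·e² therefore
scales to ±1/√2, not ±1).

**Order of operations.** Scans are averaged per sampling point first, then
binned, then normalized; positive- and negative-mode matrices are built
separately and concatenated column-wise with polarity-tagged bin identifiers.

**QC reporting.** Per-bin relative standard deviation across QC injections
and the Spearman correlation of QC intensity with run order quantify
stability and drift; the summary reports the fraction of bins with RSD below
30% (configurable). No batch correction is applied — QC statistics are
diagnostics only.

## PLS-DA and VIP

Two-class PLS-DA is NIPALS PLS1 on the autoscaled matrix with the group code
{0,1} centered. Per component: unit-norm weights `w_a`, scores `t_a = X w_a`,
X-loadings `p_a`, y-loading `q_a`, then deflation `X ← X − t_a p_a'`. The
per-component explained response sum-of-squares is `SSY_a = q_a² t_a't_a`.
Weight signs are fixed so the largest-magnitude entry of each `w_a` is
positive. Convergence tolerance is 1e-10 with a 500-iteration cap (for a
single response NIPALS converges in one pass). The default is 2 components,
matching the conventional 2-D score-plot usage in fingerprinting studies;
the count is an explicit argument.

VIP is the cumulative form over fitted components,
`VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)`, which satisfies
`mean(VIP²) = 1` exactly; with one component the VIP ranking equals the
|weight| ranking. Commercial implementations differ in whether VIP is
per-component or cumulative; the cumulative form is the standard choice and
the one implemented here.

## Marker cascade

Stage order and thresholds: VIP > 1.0, then BH-adjusted q < 0.05, then
FC > 2.0 or FC < 0.5 — all strict inequalities, so boundary values fail.
The t-test runs on ln-transformed normalized intensities (variance
stabilization) while FC is the case/control ratio of means on the linear
normalized scale. Welch's unequal-variance test is the default
(`equal_var=True` restores the pooled form). Degenerate conventions: an ion
with zero variance in both groups gets p = 1 when the means coincide and
p = 0 otherwise; FC is 1 when both means are zero and +∞ when only the
control mean is zero. FDR is applied jointly across whatever ion set is
passed; per-polarity adjustment is achieved by calling the stage per
polarity subset. Each tissue sampling point is treated as an independent
sample, matching the point-level design of the emulated study; a
patient-level analysis can be obtained by aggregating the matrix per patient
before the cascade.

## Annotation

Monoisotopic masses use the most abundant isotope of C, H, N, O, P, S, Cl,
Na, K; adduct deltas are computed from the same element masses with a
one-electron correction (proton 1.007276 Da), rather than stored as opaque
constants. Positive-mode adducts: [M+H]⁺, [M+Na]⁺, [M+K]⁺, [M−H₂O+H]⁺,
[M+2Na−H]⁺, [M+2K−H]⁺, [M+NH₄]⁺; negative: [M−H]⁻, [M+Na−2H]⁻, [M+K−2H]⁻,
[M+Cl]⁻. Matching keeps candidates within 5 ppm (default), sorted by |ppm|
with ties broken by the adduct priority order above; records not flagged as
human-relevant are excluded. The isotope check uses the first-order
approximation (M+1)/M0 ≈ n_C·0.0107/0.9893 + n_H·0.000115 + n_N·0.00364.
Identification is putative — accurate mass plus isotope ratio, no MS/MS —
and the shipped reference table is a small curated TSV of metabolites
recurrent in ambient-MS fingerprints of tissue and serum, editable by the
user; there are no live database queries.

## Diagnostic panel

The classifier is Lasso on the 0/1 response with squared loss,
`(1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁` (coordinate descent via scikit-learn,
tolerance 1e-8; λ = 0 falls back to ordinary least squares). Squared loss on
a class code — rather than logistic loss — is deliberate: it reproduces the
behaviour of the common "lasso" regression routines used for such panels,
and its score admits a meaningful fixed operating threshold. Penalty
selection uses repeated stratified random 90/10 splits (10 by default)
scored by thresholded accuracy at 0.5; ties prefer the larger penalty,
hence the sparser panel. A plain stratified K-fold mode is available. The
reported panel is the set of nonzero-weight features; restricting the design
to that active set and refitting at the same λ reproduces the scores (KKT
closure), which the suite verifies.

ROC: AUC is the Mann–Whitney rank statistic with half credit for ties; its
95% CI is a stratified percentile bootstrap (2,000 replicates, seedable).
The Youden-optimal cut-off (max sens + spec − 1, ties to higher specificity)
is reported separately from the stored operating threshold (default 0.62),
at which the confusion matrix and accuracy are computed. Note that with
aggressive penalty tie-breaking the score distribution can concentrate near
the class-prevalence intercept, so a fixed high threshold may sit above all
scores; the Youden cut-off is the data-driven alternative reported alongside.

## Serum tracking and quantitation

A tissue-selected, annotated marker is *consistent* in serum iff its serum
q < 0.05, its serum fold-change direction matches tissue, and the serum FC
clears the same 2.0/0.5 cut-offs. Unannotated markers are skipped and
counted. Concentration estimation is a single-point ratio against one spiked
standard, `c = c_std · I_sample / I_std`, on TIC-normalized intensities so
the sample's scale factor cancels. No endogenous-background subtraction is
applied to the standard — the ratio is taken literally — so estimates for
metabolites with a high endogenous level in the spiking matrix are biased
low; a calibration curve is out of scope.

## Imaging

Line scans map to pixels by row = line index and column =
`floor(speed · t / pixel_width)`, with pixel width defaulting to the line
spacing (0.2 mm, square pixels, assuming 1 scan/s at 0.2 mm/s; the scan rate
is configurable since instruments differ). Pixel intensity is the summed
peak intensity within ±tolerance (absolute Da, default 0.01 — imaging
practice at this spatial resolution, not ppm) of the target m/z; colliding
scans are averaged, unvisited pixels are zero. Origin is top-left; row 0 is
the first scanned line. No interpolation, hotspot removal, or segmentation.

## Synthetic cohorts

The generator emulates the study cohort's layout and the noise structure a
practitioner would consider realistic for droplet-spray fingerprinting; the
defaults *are* the study conditions where stated (40 patients × 2 tissues ×
3 points; 242 + 139 serum; QC every 30 runs; m/z 50–1,000 with 3,829 ions)
and otherwise fixed once at field-plausible values:

| parameter | default | meaning |
|---|---|---|
| `n_ions` | 3829 | fingerprint ions over `mz_range` (50–1,000) |
| `tic_cv` | 0.20 | CV of the mean-one log-normal per-sample TIC factor |
| `noise_sd` | 0.30 | sd of per-sample, per-ion multiplicative log-normal noise |
| `patient_effect_sd` | 0.15 | sd of the per-patient, per-ion log-normal effect |
| `drift_slope` | 1.0002 | multiplicative per-run drift (≈ +5% over 240 runs) |
| `mz_jitter` | 0.002 Da | uniform m/z jitter, bounded inside one mass bin |
| `qc_every` | 30 | every 30th run position is a pooled QC injection |

Ion centers sit on a 0.025 Da grid so bins are unambiguous; baselines are
log-uniform over three orders of magnitude. Marker ions are multiplied by
their ground-truth fold change in the case group on the linear scale before
TIC scaling, so the downstream FC estimate targets the spiked value. Patient
effects are per-ion and shared across a patient's samples, giving the paired
tissue design real within-patient correlation. QC samples are the
deterministic mean of case and control expected profiles with drift only,
mirroring pooled-serum QC practice. Scan-level jitter is multiplicative with
sd `noise_sd/2`, so the zero-noise design degenerates to exactly identical
non-marker ions. All randomness derives from one root seed through named
substreams (ion set / patients / samples), so identical designs are
bit-reproducible and any single sample can be regenerated in isolation.

What the generator does **not** emulate: in-source fragmentation and adduct
co-occurrence correlations, chemical noise and baseline ridges, detector
saturation, missing peaks, heteroscedastic mass error, or between-batch
effects beyond smooth drift. Passing tests therefore demonstrate the
pipeline's correctness and statistical behaviour under the assumed noise
model, not performance on real clinical spectra.

## Test and verification sizes

The statistical guarantees are exercised at desk scale: false-discovery
control under a global null uses 2,000 ions at 30 per group over 50
replicate cohorts; marker recovery spikes 30 ions at 4× / 0.25× among 2,000
with 60 per group; the permutation check uses 25 fresh stratified splits at
the CV-selected penalty (selection and evaluation splits are disjoint, so
the chance-level estimate carries no max-over-grid selection bias). These
sizes give the tests adequate power while keeping the default suite fast.

## Known limitations

- Profile-mode peak picking is out of scope; inputs must be centroided.
- The cascade's absolute survivor counts depend on the cohort; only the
  cascade logic and its statistical operating characteristics are
  guaranteed.
- The repeated-9:1-split reading of "10-fold cross-validation with a 9:1
  ratio" is one of two defensible interpretations; plain stratified K-fold
  is provided as a mode. Published splits of such studies (e.g., 318/63 on
  381 samples) do not always match either arithmetic exactly.
- Lasso-with-squared-loss scores are not calibrated probabilities; the
  logistic variant common in epidemiology is intentionally not the default.
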