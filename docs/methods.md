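# Methods

This note documents the models and procedures implemented in `mibci`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate about real EEG.

## Pipeline overview

Epoched two-class EEG (trials × channels × samples, labels in {1, 2}) is
band-pass filtered into four sub-bands, spatially filtered per band by CSP,
reduced to log-variance features, ranked by a feature selector, and
classified. Evaluation is stratified k-fold cross-validation in which every
data-dependent stage — CSP filters, the feature z-scorer, the selector, and
the classifier — is fitted on the training folds only.

## Filter bank

Bands: mu 8–13 Hz, low-beta 13–22 Hz, high-beta 22–30 Hz, and full-band
8–30 Hz, the rhythms modulated by motor imagery over sensorimotor cortex.
The 13 Hz and 22 Hz edges are shared between adjacent bands exactly as
specified; no gap or overlap correction is applied, and the full band is
re-filtered like the others for uniformity. The filter family is not
dictated by the band definitions, so we use the field's standard choice: a
4th-order Butterworth band-pass applied forward–backward (`sosfiltfilt`),
giving zero phase so epochs stay cue-aligned. Filtering is linear to 1e-9
and introduces no group delay (both property-tested).

## CSP

Per-trial covariances are trace-normalized before averaging within class,
making every class covariance trace-1 and scale-free across trials. The
whitening transform is the square-root form P = Λ⁻¹ᐟ² U′ of the composite
covariance's eigendecomposition — the form for which P C_c P′ = I actually
holds. The rotation B is the eigenbasis of the whitened class-1 covariance
(the standard CSP construction), filters are the columns of W = P′B ordered
by descending class-1 eigenvalue, and each filter's sign is fixed by making
its largest-magnitude element positive so fits are deterministic under
trial permutations.

Defaults: k = min(4, ch//2) filter pairs per band (8 features/band on dense
montages, 2 on 2-channel ones); variance over samples with the n−1
denominator; natural log; optional relative ridge `shrinkage` on the
composite covariance (off by default — synthetic trials are full rank; turn
it on for short trials or dense montages); a floor of 1e-300 before the log
guards zero-variance projections and is logged when hit.

Invariants asserted in tests on every fit: P C_c P′ = I to 1e-8, projected
class covariances satisfying D1 + D2 = I to 1e-6, and agreement with a
direct generalized-eigenproblem solve of (C1, C1+C2) to cosine ≥ 0.999 on
small montages.

## Feature selectors

All five return scores plus a descending order with a deterministic
tie-break (scores snapped to 12 relative digits, lower index first), and
all are column-permutation equivariant (property-tested).

**Relief-F.** Iterates over all instances (m = n, deterministic). For each
instance r, the k = 10 nearest hits and k nearest misses per class update
each feature weight by the range-normalized absolute feature difference,
down-weighted by exp(−(rank/σ)²) with σ = 50 and normalized over the k
neighbors; miss contributions carry the class-prior quotient
P(class q)/(1 − P(class r)), the form under which miss-class weights sum to
one. (The degenerate product form of the prior is available via
`miss_prior="product"` for comparison.) Constant features score exactly 0
and are excluded from the neighbor metric.

**Inf-FS.** Adjacency a_ij = λ·max(σᵢ, σⱼ) + (1−λ)·(1 − Spearman_ij) with
λ = 0.5. The pairwise-max dispersion matrix is min-max normalized to [0, 1]
rather than built on per-column-rescaled data: any per-column normalization
makes all dispersions equal and deletes the unsupervised variance signal
that lets Inf-FS find class-modulated features, while normalizing the
matrix keeps both energy terms commensurate without destroying it. Scores
are row sums of (I − rA)⁻¹ − I with r = 0.9/ρ(A).

**ILFS.** Same power-series machinery on a learned adjacency: each feature
is discretized into TT = 6 equal-frequency tokens; the total-variation
distance between its class-conditional token distributions summarizes its
evidence; a two-component 1-D Gaussian mixture fitted by EM (deterministic
initialization at the lower/upper quartiles) yields a posterior relevance
p(i) for the high-mean latent class; and a_ij = p̃(i)p̃(j) with
p̃ = p·(1 + separation) so that ordering within a latent class is resolved
by the evidence itself rather than by a saturated posterior.

**FSV.** The concave-minimization feature-selection program solved by
successive linearization: each step is a linear program minimizing
(1−α)·(mean class-1 slack + mean class-2 slack) + α·Σⱼ βe^{−βvⱼ}vⱼ subject
to unit-margin constraints and −v ≤ w ≤ v, with α = 0.3, β = 5, v⁰ = 0,
at most 20 iterations (convergence of v to 1e-6 is logged). Features are
ranked by |w|. Because the ℓ1-style penalty is sparsity-inducing, FSV
keeps one representative of a correlated informative group and may zero
the rest — it still ranks informative features above noise on average,
but is not expected to recover every member of a redundant group.

**ADM/FDM/GDM utility.** `fsv_gdm` ships the validation measures
separately from the ranking algorithm (how they would feed a ranking is
not defined, so they do not). Each series is split in the DFT domain into
DC, low and high portions at the index where the cumulative magnitude
spectrum reaches 40%, with a linear taper over Nb bins. ADM compares
pointwise intensities of the DC+low portions, FDM compares first
derivatives of the low and high portions, both normalized and scaled by
the intensity ratio c = mean|a|/mean|b| so that an identical or globally
scaled copy registers exactly zero; GDMᵢ = √(ADMᵢ² + FDMᵢ²).

**SD.** Features are quantized into qs = 4 equal-frequency bins (fewer
when the data have fewer distinct values; merges are logged) and scored by
Σ p(y,z)²/(p(y)p(z)). This form attains exactly 1 under independence —
the stated minimum — and grows to min(|Y|,|Z|) for a deterministic
relation; the unsquared sum would equal |Y|·|Z| under independence and is
therefore not used.

## Classifiers

Thin wrappers over scikit-learn behind a uniform spec: LDA (lsqr solver,
optional shrinkage), SVC with RBF kernel (C = 1, gamma = "scale"), and an
MLP with one hidden layer of ten units, 500 epochs maximum, no early
stopping, seeded. All are preceded by a StandardScaler fitted on training
data, making predictions invariant to affine feature rescaling.
`decision_scores` returns the signed distance to the boundary (LDA/SVM) or
the class-2 posterior minus ½ (MLP); score > 0 iff the predicted label is
class 2, which is what the AUROC computation consumes.

## Cross-validation

Stratified k-fold (default 5, seed 42, recorded in every report) with
shuffling. Feature selection is fitted inside each training fold by
default; `selection_scope="global"` reproduces protocols that rank
features once on all data before splitting, and is provided only as a
compatibility mode — it leaks selection information by construction.
Features are z-scored with training-fold statistics before ranking so that
Relief-F ranges and SVM/MLP scales are meaningful. Accuracy is reported in
percent, F1 with class 2 positive, AUROC via the Mann–Whitney midrank
statistic (ties ½). Per-fold train time is recorded for reporting but
never asserted on, being hardware-dependent. "Averaging over five runs"
is read as the mean over the five folds; independent repeats are available
by rerunning with different seeds.

## Synthetic data

`make_synthetic_mi` emulates exactly the structure CSP assumes: two latent
unit-variance sources band-limited to 8–30 Hz by the same Butterworth
design the analysis uses (the effect lives exactly where the pipeline
looks), with class 1 scaling source A's variance by `effect_strength` and
class 2 scaling source B's, mixed by the orthogonal factor of a seeded
Gaussian matrix (so ground-truth unmixing exists) plus i.i.d. Gaussian
sensor noise. Defaults — 60 trials/class, 8 channels, 100 Hz, 2.5 s,
variance ratio 8, noise SD 0.2 — are the study conditions for the pipeline
validity checks: the effect is unambiguous by construction so that
anything below ~100% cross-validated accuracy, or anything above chance
under permuted labels, indicates an implementation defect rather than a
hard dataset. Sources are re-standardized per trial, so `effect_strength=1`
is an exact null.

What this generator does not emulate: 1/f spectra, volume-conduction
artifacts, eye/muscle contamination, non-stationarity across trials, or
subject variability. Passing tests therefore demonstrate correctness of
the algorithms and absence of information leakage, not expected accuracy
on real recordings.

`make_planted_feature_table` plants class-shifted Gaussian columns
(means ±δ/2) among exchangeable noise columns for testing the selectors in
isolation; at δ = 0 all columns are exchangeable, giving an exact null for
hit-rate calibration.

## Numerical choices and problem sizes

- Geometric-series oracle comparisons run at damping r·ρ(A) = 0.6, where
  the tail after 50 path-length terms is ~5e-12, far below the 1e-6
  comparison tolerance; at damping 0.9 the closed form is still exact but
  a 50-term truncation is itself only ~5e-3 accurate, so the comparison
  point would measure truncation error, not implementation error.
- Monte-Carlo checks use 100 seeds for planted-selector recovery, 8–10
  permutations/seeds for chance-level nulls, and 10–20 trials/class ×
  4–8 channels for structural checks — sizes at which every statistical
  assertion holds with comfortable margin while the full suite runs in
  well under a minute.
- Eigen-decompositions use symmetric solvers (`eigh`) with explicit
  symmetrization of accumulated covariances; whitening refuses
  rank-deficient input unless shrinkage is enabled.

## Known limitations

- Binary classification only; multi-class montages require one-vs-rest
  extensions that are out of scope.
- The BCI Competition III loader supports the documented continuous
  `cnt`/`mrk`/`nfo` layout read-only; it is tested against synthetic
  fixtures in that layout, not against the original downloads. Two epoch
  window conventions exist in the literature for these recordings; the
  window is a `[t_start, t_end]` configuration knob (default 0.5–2.5 s
  post-cue) rather than a hard-coded guess.
- FSV's LP grows with trials + features; it is intended for the
  tens-of-features regime of filter-bank CSP, not thousands of features.
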