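# Methods

`mgx` implements a complete classification pipeline for two-class microarray
gene-expression data of the Lung Harvard 2 (LH2) shape: 12,533 genes per
tissue sample, 181 samples split 150 adenocarcinoma (Adeno, the
majority/positive class) versus 31 mesothelioma (Meso). The pipeline has
four stages — signal-transform dimensionality reduction, optional
bio-inspired wrapper feature selection, a seven-classifier bank, and an
imbalance-aware 10-fold cross-validation protocol with an eight-metric
confusion-matrix suite.

## Gene vectors as pseudo-time signals

Each sample's 12,533-gene intensity vector is treated as a discrete signal
with gene file order as the pseudo-time axis. File order is the only
ordering the data carries; no biological adjacency is implied, and the
window partition below is therefore a locality-preserving summarization
device, not a genomic claim.

### Window partition

All three reduction methods share one window map: `target_dim` contiguous
half-open gene ranges of width `n_genes // target_dim`, the final window
absorbing the remainder. For the LH2 shape this is 1,253 windows of width
10 with a final window of width 13, giving exactly 1,253 features per
sample for every method. How 12,533 inputs become 1,253 features is not
determined by the transforms themselves; windowed summarization was chosen
because it preserves locality, works identically for all three transforms,
and keeps each feature a direct application of the method's defining
computation. The map is exposed (`window_map`) so alternative
summarizations can be swapped in.

### Hilbert transform (HT)

The discrete Hilbert transform is computed in the frequency domain
(analytic-signal construction, `scipy.signal.hilbert`): O(N log N) rather
than the O(N²) direct convolution with 1/(πt), which is retained only as a
test oracle (explicit DFT, −i·sgn(f) multiplier, explicit inverse DFT).
The per-window feature is the mean analytic-signal envelope. Two classical
identities anchor the tests: cos → sin under the transform with unit
envelope, and H(H(g)) = −g for zero-mean signals. The discrete multiplier
annihilates the DC bin (and the Nyquist bin for even lengths), so the
involution tests use zero-mean, odd-length signals.

### Detrended fluctuation analysis (DFA)

The standard estimator: mean-center, integrate to the profile y(i), remove
a least-squares polynomial (order 1 by default, the conventional DFA-1)
from each non-overlapping segment of length s, and take F(s) as the RMS of
the residuals pooled over all points of all segments. The scaling exponent
α is the least-squares slope of log F(s) on log s. The pooled-RMS reading
was chosen over a literal "sum of r(i)² over segments" (which omits the
inner per-segment mean) because only the pooled estimator yields the
canonical calibration α ≈ 0.5 for white noise and α ≈ 1.5 for its
cumulative sum, which the tests verify at n = 4096 over 20 seeds. If the
detrended residuals vanish at (nearly) all scales — e.g. a constant input,
whose profile is identically zero — α is undefined and a degeneracy error
is raised. Note that a *linear* input is not degenerate: its profile is
quadratic, survives linear detrending, and yields a trend-dominated
α ≈ 2. The per-window DFA feature is the RMS of the order-1-detrended
profile within the window — a local fluctuation; a scaling exponent would
be ill-posed on 10 points.

### Least-squares linear regression (LSLR)

Ordinary least squares with intercept, solved by the normal equations, with
the sum of squared errors evaluated at the solution. Rank-deficient designs
raise an error naming the dependent columns (via pivoted QR). The
per-window feature is the RMS residual of a straight-line fit to the raw
intensities in the window; windows of width ≤ 2 are interpolated exactly
and contribute zero.

## Synthetic data generator

Per-gene intensities are log-normal: gene g has a baseline log-intensity
drawn from N(4, 1), and each observation adds N(0, noise_sd²) log-scale
noise. This yields strictly positive, positively skewed, heavy-tailed
intensities on the hundreds scale — the qualitative shape of raw microarray
fluorescence. Class structure is a location shift of `effect_size` log
units applied to the Meso samples of `n_informative_blocks` contiguous
blocks of `block_width` genes (defaults 20 × 50 against noise_sd = 1), so
window-based reduction can detect it; block coordinates are recorded in the
output metadata for recovery scoring. Defaults reproduce the LH2 cohort
shape (12,533 × 150/31).

What the generator does **not** emulate: batch effects, probe-level
artifacts, inter-gene correlation beyond the planted blocks, and the actual
LH2 expression values. Tests passing on this generator therefore
demonstrate the machinery's correctness and its behaviour under controlled
signal, not performance on real microarrays; the published LH2 headline
numbers are consequently validated through confusion-matrix reconstruction
and aggregation of the printed tables rather than by re-running the
external dataset.

## Wrapper feature selection

Agent positions live in [0, 1]^d and binarize to a feature mask by
thresholding at 0.5 (the simplest monotone mapping; configurable). Fitness
is the MSE of a nearest-centroid surrogate regressor — a sample at the
Adeno centroid maps exactly to the Adeno target 0.95, at the Meso centroid
to 0.1, in between proportionally to relative distances — evaluated on an
internal deterministic 3-fold split of the training partition, so optimizer
fitness never sees the outer test fold. The surrogate is deliberately cheap
(population × iterations evaluations) and is memoised per mask. An empty
mask scores +∞ and can never become the best.

**EHO** (elephant herd): every agent moves a fraction α = 0.65 of the way
toward the herd best (per-dimension uniform random modulation); the best
agent is replaced by β = 0.68 times the herd centroid; the worst agent is
re-seeded uniformly over the widened range [x_min, x_max + (x_max − x_min)]
and clipped back into bounds (the widening term otherwise escapes the
search box). A single herd is used — no clan structure — matching the
update equations as printed. **CS** (cuckoo search): nests move under
personal-best and global-best pulls (both coefficients 1.0) plus a
Lévy-scaled Gaussian perturbation, with step s = σ·r^(−1/μ), σ = 1,
μ = 1.3 — an exact power-law tail, P(S > t) = (t/σ)^(−μ); each iteration
the worst p_a = 0.4 of nests is abandoned and re-seeded while the best nest
is retained. The four-name/three-value parameter listing for CS is resolved
as p_a = 0.4 (abandonment), step scale 1, Lévy exponent 1.3, and the
global-pull coefficient set equal to the local one.

Both optimizers are elitist — the global best is tracked outside the
population, so the best-fitness history is monotonically non-increasing by
construction, and identical seeds give identical masks. Desk-scale budgets
(population 50, 200 iterations) preserve the optimizers' qualitative
properties — recovery of a unique known optimum in ≥ 18/20 seeds and
over-selection of planted features — at a cost that fits a laptop; the
full-scale budget (population 1253, 1000 iterations) sits behind
`paper_scale=True`.

Whether selection belongs inside or outside the CV loop is a genuine
protocol ambiguity; the default runs it inside each training partition
(leak-free), with `fsel_global_mode=True` reproducing the laxer global
alternative.

## Classifier bank

**BLDC** — per-class Gaussian discriminant g_y(x) = −½ log|Σ_y| −
½ (x−μ_y)ᵀ Σ_y⁻¹ (x−μ_y) + log P(y), implemented directly. With up to
1,253 features and ≤ 181 samples the class covariances are singular, so a
ridge of 1e-3 × mean diagonal is added (configurable); the tuned "class
mean = 0.85, 0.1" values are read as continuous-score targets, not as fixed
class means — means are always estimated. **NBC** — Gaussian naive Bayes in
log space with a variance floor of α = 0.01 times the largest pooled
feature variance, and a Meso prior of 0.2 (minority), Adeno 0.8. Both are
pure-log-domain and survive features scaled by 10⁶.

**DT / RF / SVM** delegate their solvers to scikit-learn (an established QP
and tree implementation) behind the bank's uniform surface, with the
defining primitives — Gini impurity, information gain, majority vote, the
RBF kernel — implemented and tested in-package as contracts. Tuned
hyperparameters: DT depth 10; RF 100 trees, depth 10, 25 % bootstrap
(converted to an absolute draw count per fit; an absolute count can be
configured directly); SVM linear C = 0.85, polynomial C = 0.76, γ = 10,
degree 3 (degree is not specified anywhere, 3 is the package default),
RBF C = 1, γ = 100. The tree split criterion is Gini: the listed "MSE"
criterion is a regression loss and not meaningful for classification
splits. A single printed class weight is interpreted as the positive
class's share, the complement going to the other class. Note that γ = 100
and the BLDC ridge were tuned to LH2's feature scale; on differently scaled
data (including the synthetic cohorts in the test suite) scale-matched
values are passed through the same config fields.

Every model exposes a continuous score: posterior probability (BLDC/NBC),
sigmoid-squashed margin (SVM), or positive-class probability (trees,
scikit-learn's vote-probability aggregate standing in for the raw vote
fraction), affinely mapped onto [0.1, 0.95] so MSE monitoring and optimizer
fitness operate on the target scale. Prediction ties break toward Adeno,
the majority class.

## Evaluation protocol

**Targets.** The regression targets 0.1 (Meso) and 0.95 (Adeno) satisfy the
mapping constraints: both in (0, 1), Adeno the upper target, separation
≥ 0.5; `validate_targets` enforces all three and the optional class-mean
bounds.

**Imbalance scheme.** Stratified 10-fold CV (the minority class has only
31 samples; unstratified folds can hold ≤ 2 Meso and destabilize the
minority model). Per fold, two models are fitted on the training partition:
model I scores Adeno membership (output A0), model II scores Meso
membership (M0), and each test sample is assigned by argmax(A0, M0), ties
to Adeno. Fold confusions are summed into one pooled confusion matrix
(pooling, rather than per-fold averaging, is what reproduces the printed
MCC/JI/CSI/kappa self-consistently). Per-fold fitting is a pure function
of the training partition; the leak-audit test perturbs test-fold features
(labels fixed, so the stratified split is unchanged) and asserts the
fitted masks, parameters and predictions are identical.

**Metric suite.** Adeno is positive. Accuracy, F1, error rate, Jaccard,
CSI (= precision% + sensitivity% − 100) and g-mean (= √(sens·spec), percent
scale) on 0–100; MCC and Cohen's kappa as ratios. Kappa is the standard
(p_o − p_e)/(1 − p_e) with chance agreement from the marginals — this
normalized reading reproduces the benchmark tables' printed kappas (e.g.
0.7203, 0.73206) exactly on the reconstructed matrices. MCC uses the
standard four-factor denominator. Metrics with vanishing denominators are
reported as NaN and flagged, never silently zeroed. Known caveat: the
benchmark tables' printed g-mean cells are not consistent with any integer
confusion matrix matching their own (Acc, F1) pairs (e.g. 86.68 printed
where the unique matrix gives 84.40); g-mean is implemented from its
formula and excluded from reconstruction checks.

**Confusion-matrix reconstruction.** Given a printed (Acc %, F1 %) pair at
two decimals and the cohort margins (181; 150/31), exhaustive search over
tp ∈ [0, 150], fp ∈ [0, 31] recovers the matrix; both round-to-nearest and
truncation are accepted since published tables mix them. The match is
provably unique for the benchmark rows used; near-perfect matrices
(≥ 180/181 correct) can be ambiguous at two-decimal F1, in which case an
ambiguity error lists all candidates rather than guessing.

## Numerical choices and edge cases

- Population (divide-by-N) variance for descriptive statistics; documented
  because either convention is defensible.
- CCA on wide blocks is rank-deficient; a 1e-6 ridge on the block
  covariances with a logged warning. Between-class CCA aligns the class
  blocks on the feature axis (observations = features), the only alignment
  available with unequal class sizes.
- Skewness of exactly constant data is reported as 0 by convention;
  kurtosis is flagged degenerate.
- All randomness flows from a single integer seed (`RunConfig.seed`);
  derived fold and optimizer seeds stay below 2³¹.
- DR outputs are cached by content hash inside a process, since they are
  classifier-independent; the full grid reuses them.

## Problem sizes used in the test suite

Unit and acceptance tests run on synthetic cohorts of 200–1,000 genes with
50–100 windows and 40–80 samples, desk-scale optimizer budgets
(population ≤ 50, ≤ 200 iterations), 20-seed Monte-Carlo checks for the
DFA calibration and planted-feature recovery, and one full-size
(12,533-gene) cohort for the window-arithmetic check. These sizes were
chosen so the whole suite exercises every code path in a few minutes while
the statistical assertions retain comfortable margins.

## Known limitations

- The windowed summarization is a reconstruction of an unspecified step; a
  different aggregation would change feature values (not counts).
- The surrogate fitness is not the downstream classifier; masks are tuned
  for centroid separability, which correlates with but does not equal
  per-classifier accuracy.
- The generator's planted-block model makes recovery easier than real
  co-expression structure would; recovery rates on real data will be lower.
- Published LH2 cell values outside the reconstructed rows (e.g. Table-1
  style descriptive statistics of the real dataset) are not reproduced
  here, as they require the external download.
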