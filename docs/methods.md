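# Methods

## Statistical model

All interaction tests are saturated Poisson log-linear models on cell
counts of binary cross-classifications, fitted in closed form.

**Two-way (within-gene).** For one gene in one cohort the 2×2 table
cross-classifies mutation (0/1) against CNA state (wild-type/altered).
The saturated model `N ~ mut + CNA + mut:CNA` with Poisson family and log
link has MLE interaction coefficient

    ψ̂ = ln( n11·n00 / (n10·n01) ),   SE(ψ̂) = sqrt( Σ 1/nij ),

i.e. the log odds ratio and its Woolf standard error. The test suite
verifies this identity against an iteratively fitted GLM to 1e-6 on
thousands of random tables; the closed form is the implementation, the
iterative fit only an oracle. p-values are two-sided Wald normal tails,
matching the regression-summary convention. With a zero cell and zero
pseudocount the term is reported *non-estimable* rather than silently
regularized — two-way fits default to pseudocount 0 so that regularization
is always an explicit choice.

**Copy-number masking.** CN states are GISTIC-threshold integers in
{−2…+2}. The loss-model table includes only samples with CN ∈ {0, −1}
(altered = −1): gains are a different biology and deep deletions would
conflate one-copy loss with biallelic deletion. The gain-model table
includes CN ∈ {0, +1, +2} (altered ≥ +1). The source descriptions of broad
loss are internally inconsistent (≤ −1 vs = −1); we follow the explicit
model definition (= −1) and expose `loss_includes_deep=True` for the ≤ −1
variant throughout.

**Three-way (modifier).** Stratifying the 2×2 table by a second gene's
mutation status (its copy number is deliberately ignored, to avoid
confounding by overall CNA burden) gives a 2×2×2 table whose highest-order
coefficient is

    τ̂ = ln( OR₁ / OR₀ ),   SE = sqrt( Σ over all 8 cells 1/ñij ),

the log ratio of stratum odds ratios, computed on cells with a default
pseudocount of 1 (zero cells are routine in the sparse stratum). τ̂ is
implemented as the difference of stratum log-ORs, so the identity
"three-way coefficient = stratum-1 two-way − stratum-0 two-way" holds
exactly in floating point. The tissue contrast is the same model with
cohort membership (detected cancer type vs pooled other eligible cohorts)
as the third factor, also with pseudocount 1. Stand-alone odds ratios for
volcano-style effect sizes use the Haldane–Anscombe pseudocount 0.5.

**Sign convention.** All coefficients are co-occurrence oriented: positive
means mutation and the altered CN state co-occur. Report tables also carry
`coef_signed_by_cn` (loss negated) mirroring the display convention in
which stronger mutation/loss co-occurrence is more negative.

## Permutation null and FDR

Mutation, CNA-loss and CNA-gain events are three separate binary
sample × gene matrices per cancer type, each randomized independently by
repeated 2×2 checkerboard swaps ([[1,0],[0,1]] ↔ [[0,1],[1,0]]), which
preserve every row and column sum exactly. The default burn-in is 10× the
number of 1s. Index proposals come from an inline xorshift64* generator
(deterministic per seed); the proposal is symmetric and the swap is an
involution, so the stationary distribution is uniform over the fill class
— verified by chi-square against brute-force enumeration on small
fixtures. Because the three classes are permuted independently, a permuted
(sample, gene) can carry both a loss and a gain event; such cells are
re-encoded as CN −2, which the masking rule excludes from both model
tables. Real deep deletions are likewise not a permuted class: they are
excluded from every table and enter the event tracks as zeros.

FDR at p-value cutoff c is (mean permuted detections at c) / (real
detections at c), on the grid of distinct real p-values (the curve only
changes there), estimated jointly across all eligible gene–cancer pairs
within one model family (loss, gain, tissue, three-way), 100 permutations
by default. A running minimum from the largest cutoff downward makes the
reported curve monotone; calls at target q are all results with p ≤ the
largest cutoff whose adjusted FDR ≤ q. Cutoffs with zero real detections
carry NaN. This permutation-count estimate is the primary inference path;
BH-style analytic corrections are intentionally not used for calls.

## Cohort construction and QC

Samples must be present on both platforms (appear in the mutation table
and in the CN matrix), must not be on the QC exclusion list, and must not
be hypermutated: variant count strictly above Q3 + 1.5·IQR of the cohort's
per-sample non-synonymous counts, with linear-interpolation quantiles
(the common default; the quantile type was an open choice). The
hypermutator count is taken before any mutation-class filter. Genes are
restricted to the driver catalog. A gene–cancer pair enters the two-way
screen when its mutation frequency is strictly greater than 2% of the
QC-passing cohort (the denominator was an open choice; post-QC samples are
used since all analyses operate post-QC). Third-order partners use an
inclusive ≥ 2% threshold — both thresholds follow their respective
definitions' wording. Non-synonymous classes are PTV (nonsense,
frameshift, splice-site), deleterious missense (at least one of
SIFT/PolyPhen2 deleterious/damaging), other missense, and in-frame indel;
the class map is configurable because MAF dialects differ, and any class
subset can drive the mutation indicator for robustness re-runs.

## Synthetic cohorts

The generator emulates exactly the statistical structure the screens
assume. Each gene has configured margins (p_mut, p_loss, p_gain) and a
planted log odds ratio ψ per CNA mode; per sample, (mut, CN) is drawn from
the 2×2 joint whose p11 is the feasible root of the odds-ratio quadratic,
so margins and ψ are matched exactly in expectation. Loss and gain are
mutually exclusive per sample, mirroring thresholded CN states; when both
modes are active their joints with mutation are set marginally. A gene
with modifier B draws its cells with ψ (B unmutated) or ψ + τ (B mutated),
planting a three-way coefficient of exactly τ; modifier chains are
rejected. CN is emitted as −1/+1 (no deep/high states, no segment-level
correlation between genes, no mutation signatures or positions — passing
tests therefore demonstrate calibration and recovery under the model's
own assumptions, not robustness to real-data artifacts such as correlated
CNA segments or subclonality). An optional hypermutator injection appends
samples mutated in every gene to exercise the QC filter. Cohorts round-trip
through the real file readers (MAF-style table, CN matrix, catalog TSV).

## Validation studies and problem sizes

`hitswitch.studies` packages the validation experiments used by the test
suite and `scripts/acceptance.py`:

- **Null calibration** — 20 independent null cohorts (200 genes, 1,000
  samples, margins 0.2/0.2, ψ = 0), two-way loss fits, 100 permutations:
  the fraction of two-sided p < 0.05 should be nominal, and the
  *false-call ratio* — calls admitted at FDR 10% divided by nominally
  significant (p ≤ 0.05) null tests — should be near zero. This ratio is
  the study's false-call metric because on null data every admitted call
  is false and the nominal hits are the pool the procedure must reject.
- **ψ recovery** — planted ψ ∈ {−2,−1,0,1,2} at n = 2,000, 200 replicate
  genes each: mean bias of ψ̂ and 95% Wald-interval coverage.
- **τ ranking** — 50 replicate cohorts with a planted τ = −2 modifier
  among ~10 candidate partners: fraction of screens ranking the true
  modifier first by |τ̂|.

These sizes keep the full suite under a minute on one CPU while leaving
Monte-Carlo error well inside the asserted bands.

## Numerical and design notes

- Seeds: every stochastic stage derives independent 31-bit child seeds
  from the master seed via `numpy.random.SeedSequence`; per-cancer-type
  permutation streams are offset by a CRC32 of the cohort label, so runs
  are reproducible regardless of cohort iteration order.
- Degenerate inputs: all-zero event matrices permute to themselves;
  conditional frequencies return NaN on empty strata; empty partner lists
  yield empty screens; an empty post-QC cohort is an error.
- Functional-sharing test: score = number of shared annotation terms
  (simplest score consistent with "shares functions and pathways"; Jaccard
  available), compared between interacting and background pairs by a
  two-sided Mann–Whitney U with tie correction; the default background is
  all unordered catalog pairs of the cancer type minus the interacting
  pairs.
- The driver-class report is a pure function of the significant-call
  multiset; classification defaults to calls at FDR 10% (the sensitivity
  threshold of 20% is a configuration option).
- Tissue contrasts report two-sided p plus the signed contrast rather than
  a directional test, since directionality is better judged from the sign.
- Known limitations: no exact (Fisher/Barnard) inference; no continuous
  CN dosage; no segment-level CNA correlation in the simulator; pooling
  scope of the FDR (across cancer types within a family) is a convention,
  as is estimating the three-way null by permuting matrices while holding
  the test list fixed.
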