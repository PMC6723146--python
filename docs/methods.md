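# Methods

## The data model

One condition (a tumor nodule, a resection margin, a cell line) is
profiled in λ ≥ 4 biological replicas — parallel culture dishes or
quarters of a tissue sample, regarded as the same system under slightly
different conditions.  Input is probe-level: each spot carries a
foreground and a background fluorescence per replicate and a
pixel-quality flag, and a gene may be probed by up to ~28 redundant
spots, as on Agilent 4×44k-style two-color arrays.  The package models a
single net intensity per spot per replicate; the two dye channels are
assumed to have been reduced to one net value upstream by the feature
extraction software.

QC removes control spots, spots with a corrupted/saturated pixel in any
replicate, and spots whose foreground is less than twice the background
in any replicate (a spot with fg exactly = 2·bg is retained; removal
requires strict inequality).  Survivors get net = fg − bg, strictly
positive by the low-signal rule.  Each replicate is then divided by its
median gene-level expression, so all downstream quantities are in
*median units* (median quantified gene = 1).  This median scaling is the
simplest transform consistent with that unit convention; lab-specific
normalization chains (dye-bias loess, quantile) are deliberately out of
scope, and users of real arrays should expect normalization differences
to move absolute GCH values.

## Stability: REV and RES

A gene's expression control is measured by its pooled coefficient of
variation across replicas.  Per probe, CV = s/μ on the linear scale
(sample SD, λ−1 denominator); the gene pools its probes in quadrature
and applies the chi-square mid-interval correction

c(r, ε) = ½·( √(r/χ²(r; 1−ε/2)) + √(r/χ²(r; ε/2)) ),  r = λR − 1,

the average of the two ends of the (1−ε) confidence interval for an SD
estimated with r degrees of freedom.  c > 1 always and decreases toward
1 as r grows, so sparsely probed genes are penalized for the uncertainty
of their CV estimate.  ε defaults to 0.05 on the supported grid
{0.01, 0.025, 0.05, 0.1}; smaller values are swamped by technical noise.
Note that published descriptions of this coefficient sometimes quote a
range dipping below 1 for highly redundant probes; no reading of the
mid-interval formula can produce values below 1 (each term is a ratio of
r to a quantile that brackets r), so this package treats the formula as
normative and documents the discrepancy rather than chasing the quoted
endpoints.

RES_i = ln(⟨REV⟩/REV_i) rescales against the condition's median gene.
Genes with zero pooled CV (constant expression) would make RES and GCH
infinite; they receive half the smallest positive REV in the dataset and
are flagged (`rev_floored`), preserving their "most stable" rank.

## Coordination power

Pearson correlations are computed between log2 gene-level (probe
averaged) expressions across the λ replicas, for all N(N−1)/2 pairs.
CP_i is the mean of ρ² over the gene's N−1 pairs; the self pair is
excluded.  With λ = 4 the null expectation of ρ̂² is 1/(λ−1) = 1/3 and a
single pair is nearly uninformative (the two-sided critical |ρ| at
α = 0.05 is 0.95); the method's power comes from aggregating squared
correlations over hundreds of pairs, not from per-pair testing.  Pair
labels (synergistic / antagonistic at the t-based critical value,
independent below |ρ| = 0.05 — the 0.05 is this package's operational
choice) are offered for reporting, not inference.

The all-pairs computation is blocked (`block_size` rows of the
correlation matrix at a time, default 512): memory stays
O(block_size × N) while the result equals the dense computation exactly.

## GCH and the GMR call

The default form is GCH_i = (⟨REV⟩/REV_i)·exp(4·CP_i): a stability
ratio times a coordination factor bounded in [1, e⁴ ≈ 54.6].  This is
the closed form whose scale matches published master-regulator
hierarchies (dominant genes scoring ~40–170).  The alternative
`exact_ratio` form exp(RES_i + CP_i/⟨CP⟩) normalizes coordination by the
condition's grand-mean CP; the two coincide only when ⟨CP⟩ = 1/4, which
the λ=4 null (⟨CP⟩ ≈ 1/3) does not satisfy, so the forms differ in scale
while agreeing on ordering within a condition.  Ranking breaks GCH ties
alphabetically.  The GMR is the rank-1 gene; it is called *actionable*
when top/second GCH ≥ 1.5 — the threshold is this package's
operationalization of "clearly dominant" (published examples: a 1.71×
gap treated as actionable, ~1.0× not), not a significance test.

Regulation calls between two aligned conditions use the signed ratio
x (x = μc/μn if cancer is higher, −μn/μc if lower, +1 at equality) and
the gene-specific threshold CUT = 1+√(2(REV_c²+REV_n²)); the call is by
|x| > CUT alone.  The Welch p-value (computed on replicate-level gene
means — biological replicas are the unit of inference) is reported and
enters only the WPR weighting.  WPR's magnitude term defaults to |x|−1,
symmetric and zero at no change in either direction; the literal |x−1|
variant (which scores an unchanged down-direction gene as 2) and a
pathway-average-GCH weight variant are available as options because both
appear in circulating implementations of the method.  No
multiple-testing correction is applied: the call criterion is CUT, and p
only modulates WPR.

## The synthetic-data generator

The generator emulates the features of replicated array data the method
actually exercises: probe redundancy (R ~ truncated Geometric(0.45) on
1..28, mean ≈ 2.2), lognormal abundance (log2 SD 1.5 around the median
gene), per-gene noise heterogeneity (spot-level log2 SD drawn from
U(0.2, 0.6)), fixed per-probe affinity offsets (log2 SD 0.25), a shared
per-replicate latent factor, intensity scaling with additive background,
control spots (1%) and sporadic bad pixels (0.2% of spots).

Design choices that matter:

- **Noise placement.** The per-gene noise SD applies independently per
  spot × replicate (hybridization noise).  This matches the pooled-CV
  estimator's degrees-of-freedom accounting r = λR−1, which assumes
  independent spots.  Biological replicate variation that is shared
  across a gene's probes is carried only by the latent factor; fully
  probe-shared per-gene noise is not modeled, and with it the effective
  df of the pooled CV would collapse to λ−1 regardless of R.
- **Standardized loadings with balanced signs.**  A gene's loading ℓ is
  its correlation with the per-replicate factor (factor coefficient
  σ·ℓ/√(1−ℓ²)); 30% of genes are loaded, |ℓ| ~ U(0.3, 0.7), with random
  signs so modules contain both in-phase and antiphase members.  Signs
  are balanced for a further reason: a one-signed factor shifts each
  replicate's *median*, and the median normalizer would then inject an
  anti-factor component into every gene — a real finite-panel artifact
  that at 500 genes measurably inflates the most stable genes' REV.
- **The planted GMR** (gene G0000) combines a ×20 baseline, residual SD
  0.02 log2, loading 0.8 and 8 probes: simultaneously the most stable
  and among the most coordinated genes, which is the configuration the
  method predicts for a master regulator.
- **Stream splitting.**  Every gene draws its parameters and noise from
  its own seed-sequence stream ([seed, purpose, gene]); enlarging a
  config never reshuffles existing genes, and paired conditions share
  parameter streams while drawing independent noise.

Planted-regulation pairs multiply a random gene subset's baseline by
fold-changes with random direction; ground-truth labels are returned for
sensitivity/false-positive accounting.

## Simulated perturbations

`simulate_perturbation` shifts a target gene by δ log2 units and every
other gene by ρ_tj·δ·(s_j/s_t) — the regression-slope response on the
log2 scale, with ρ from the same dataset and the SDs pooled over each
gene's redundant probes (RMS of per-probe log2 replicate SDs, the REV
estimator's pooling; at λ=4 a plain gene-level SD has 3 df and its lower
tail makes the slope denominator explode).  Shifts are clipped at ±64
log2 units purely as a numerical guard.  **This propagation rule is this
package's own minimal model** — the real claim is established by
transfection experiments, and the rule exists only to make the
"higher GCH ⇒ larger consequences" property testable in software.  The
crossed two-cell-line harness plants two strong (stable, loaded) and two
decoy (noisy, uncoordinated, σ = 0.5 log2) genes at the same expression
level, mirrored between the lines, perturbs each gene in both lines
(δ = 2) and checks that the larger transcriptome-wide WPR lands in the
line where the gene's GCH is higher.

## Problem sizes and measured behavior

The validation suite uses 500-gene panels (2000 for the independence
null), 200 seeds for planted-recovery estimates and 50 seeds for
concordance and null calibration — panels small enough to iterate on
while preserving every structural feature the estimators touch.  Two
behaviors deserve explicit mention:

- Planted rank-1 recovery at the 500-gene default measures ≈ 0.90 over
  800 simulations — at, not comfortably above, the 90% design goal.  The
  limiting terms are the 3-df sampling noise of the planted gene's
  shared-factor variance and the finite-panel noise of the median
  normalizer (≈ 0.02 log2 at 500 genes, comparable to the planted gene's
  total SD; at 2000 genes recovery rises to ≈ 0.94).  Real arrays
  quantify 12 000+ genes, where the normalizer term vanishes.
- Under the null (no planted regulation) the regulation caller is well
  calibrated (false-positive rate ≈ 3% against the CUT thresholds) and
  mean CP sits at 1/3, but the mean pathway WPR is ≈ 0.3–0.4, not ≈ 0:
  with per-replicate CVs in the generator's 0.15–0.45 band, the null
  |x|−1 term averages ≈ 0.1–0.2, and the μ^(normal) weight (mean > 1
  for any lognormal abundance law) scales it up.  WPR is a magnitude
  meter, not a calibrated test statistic; it separates regulated from
  unregulated gene sets by an order of magnitude (see
  `examples/02_compare_conditions.py`) but its absolute null level
  tracks the noise band of the data.

## What passing tests do and do not show

The generator produces clean lognormal noise, a single latent factor and
exact background subtraction.  It does not emulate dye bias, spatial
artifacts, cell-type mixtures within a sample, heavy-tailed outliers or
cross-hybridization.  Passing the planted-recovery and concordance
suites therefore shows the estimators and their interplay are
implemented correctly and behave as designed under the stated model —
not that GCH rankings from any particular real array are biologically
correct.  Published GCH tables from real tumors additionally depend on
an unpublished normalization protocol and are explicitly not reproduced
here (the cross-condition table machinery guarantees their *shape*
only; `examples/convert_geo_series_matrix.py` is provided, clearly
marked non-validated, for users with local copies of the deposited
arrays).

## Degenerate inputs and tie-breaks

Zero-variance genes: REV floored and flagged; excluded from coordination
(ρ undefined) with N reduced.  Welch test with zero variance on both
sides: p = 1 for equal means, 0 otherwise; the call path rescales each
gene's values (the test is scale-invariant) so extreme simulated
fold-changes cannot overflow the df computation.  Equal means across
conditions: x = +1 (the ratio branches leave equality undefined).
Partner ranking and gene ranking break ties by gene symbol, making all
outputs permutation-invariant and reruns byte-identical.
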