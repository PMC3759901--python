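# Methods notes

This note records the statistical model behind `maidflow`, the
parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical decisions taken where the design was open.

## Preprocessing model

**Detection censoring and linear conversion.** TaqMan threshold cycles
above the detection limit (default Ct 38, including the instrument's
Ct 45 "undetermined" sentinel) are floored to the limit and flagged
undetected; detected values map through S = 2^(−Ct) × 10⁹. The
scale factor 10⁹ is fixed by the conversion's own anchor values
(Ct 38 ↦ 0.004, Ct 20 ↦ 953); a literal reading of the equation with
10^−9 would contradict both anchors, so the implementation uses the
internally consistent constant. One cycle corresponds to a twofold
signal change, and the censoring floor (0.004) is the lowest signal the
pipeline ever reports.

**Cyclic loess.** Within each normalization group — one patient's
samples on one card for the PCR cards, all samples jointly for
intensity arrays — every sample pair contributes a loess fit (span
0.7, local linear) of M against A on the log2 scale; sample i receives
−fit/2 and sample j +fit/2. All pairwise corrections within a cycle
are computed from a common snapshot and averaged over each sample's
n−1 pairs, which makes the result independent of column order (a
sequential in-place sweep is not) and exact for two-sample groups. One
cycle shrinks constant sample offsets by about half toward the group
mean; an `iterations` parameter is available where stronger convergence
is wanted. Undetected wells are excluded from curve fitting but still
transformed. Local fits are interpolated over 1% of the A-range (the
standard lowess `delta` speedup).

**Quantile anchoring.** Per card, each patient's pooled signals are
multiplied by one scalar so every patient's 95% quantile equals the
cross-patient median of pre-scaling quantiles, taken on the log scale
(for an even number of patients this is the geometric mean of the two
central quantiles, keeping scale factors symmetric in log space). The
operation preserves within-patient ratios and is idempotent.

**CV convention.** Coefficients of variation use the sample (n−1)
standard deviation over the mean on the linear scale, censored wells
included at the floor signal; features with zero mean are excluded
from the mean CV. The QC report emits the mean CV at three stages
(raw linear, post-loess, post-anchoring). On cohorts whose
between-patient biases are mild, anchoring can slightly *raise* the
mean CV: wells censored to a common floor are exactly equal before
scaling and acquire the between-patient scale factors afterwards. The
CV-reduction property is asserted where it is well posed — groups with
injected multiplicative sample biases.

## MAID scoring and filtering

The spread of the log2 ratio M decreases with mean log intensity A.
Per (patient, comparison) array pair, usable features are sorted by A
into up to 20 equal-count bins; the per-bin sample SD of M (optionally
1.4826×MAD with `robust_spread`) is fitted by constrained nonlinear
least squares to f(A) = a·exp(−b·A) + c with a, b ≥ 0 and c ≥ 10⁻⁶.
Numerical choices: the fit runs in shifted coordinates A′ = A − min(A)
(the family is shift-invariant and the exponential stays O(1) over the
data range, which matters because linear PCR signals below 1 give
negative A); starts are taken from b₀ ∈ {0.1, 0.3, 1, 3}; if every
start fails, a monotone non-increasing isotonic interpolation of the
bin spreads is used and flagged in the diagnostics. Only features
quantified on *both* sides of a comparison inform the curve:
half-censored log-ratios are truncation artifacts of the detection
floor, not measurement spread, and including them flattens the curve
and mis-calibrates scores across the abundance range (half-censored
features are still scored). Both-censored features carry no evidence
and always score 0.

The score is the ratio M / f(A). It is antisymmetric under swapping
treated and baseline, which also means the spread curve depends only on
the unordered sample pair — the permutation test exploits this by
precomputing scores for all C(T,2) pairs per patient and reducing each
relabeling to tensor lookups; this reformulation is exact and is
verified against the direct recompute path in the tests.

Cutoffs are mandatory study parameters: the shipped profile uses C = 2
for mRNA and C = 1 for miRNA (the higher miRNA spread curve already
demands larger fold changes), with k = 4 of 6 patients. A feature
passing up at one comparison and down at another appears in both union
lists and is flagged as a conflict.

## Permutation test

The test statistic is the size of the union of up- and down-filtered
sets over all post-baseline comparisons. The null rearranges each
patient's time labels independently and uniformly (identity included)
and recomputes everything; p = #{null ≥ observed}/n_perm, with an
optional add-one estimator. A single seeded generator drives all
draws. On pure-null synthetic cohorts the p-value is approximately
uniform (the acceptance suite checks the fraction at p ≤ 0.05 over 100
cohorts against a binomial band), and on a small instance the
Monte-Carlo p agrees with exhaustive enumeration of all joint
relabelings within ±0.02.

Calibration experiments run on Ct→linear converted cohorts without
loess/quantile anchoring: within-patient log-ratios are invariant to
per-(patient, card) scale factors, so those stages cannot change the
statistic's null behaviour, and skipping them keeps 100-replicate
experiments fast on one CPU.

A note on the pure-null filter rate: with perfectly calibrated scores
(unit-variance Gaussian ratios, three comparisons sharing the baseline
sample), the union rule at C = 1, k = 4 of 6 passes ≈ 4.0% of usable
features by direct Monte Carlo — about 2.8% of a 651-feature card
cohort. The implementation reproduces this ideal rate, and the unit
test asserts agreement with that oracle. Observed data with genuine
signal yield lower *relative* null rates because the signal features
inflate the fitted spread curve in every permutation.

## Downstream statistics

Paired t-tests are classical two-sided tests on patient-wise
differences (n−1 df); zero-variance differences yield an undefined
sentinel rather than a fabricated p. The α = 0.10 validation screen is
a plain per-feature threshold, deliberately uncorrected — it is a
reporting convention for a five-candidate confirmation experiment, not
a discovery procedure. Spearman's rho uses mid-ranks on ties.
Heat-map layout: rows are z-scored (mean 0, sample SD 1; constant rows
flagged and zeroed), and rows and columns are ordered by single-linkage
hierarchical clustering with distance 1 − Pearson r; constant rows are
excluded from the distance computation and appended last. Images are a
convenience; the merge trees and leaf orders are the tested artifact.

## Target network

Edges come from prediction-consensus records (kept at ≥ 5 of 10
algorithms) and experimentally validated records (kept regardless of
consensus); both endpoints must have passed their MAID filters
(case-insensitive identifier match — the module expects identifiers
pre-harmonized between assay names and database keys). An edge with
both kinds of support counts once in the edge total and once in each
evidence tally. Filtered features without any retained edge are not
network nodes. Raising the consensus threshold can only remove edges.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the chemistry of any platform:

- **Abundance**: a two-component mixture. Features expressed in the
  assayed tissue draw log2 signals from Normal(−2.5, 4.5) (detected
  threshold cycles spanning ≈ 13–38); absent features sit ~7 log2
  units below the detection floor, so their wells are undetermined.
  The absent weight is solved so the expected fraction of wells beyond
  Ct 38 equals `frac_undetected` (default 0.38, matching ≈ 400 of 651
  assays detected); a 41-node Gauss–Hermite quadrature accounts for
  the expressed component's own censoring tail. The mixture reflects
  the bimodal Ct distributions real cards show; a single Gaussian
  centered to give the same censoring rate would pile features onto
  the detection boundary and overstate censoring artifacts.
- **Noise**: `spread_params` (default a = 0.37, b = 0.12, c = 0.25)
  parametrize the *fold-change* spread curve s(A) — the SD of a null
  feature's log2 ratio between two samples — so each individual sample
  carries Gaussian noise s/√2 and the curve estimated from MA clouds
  recovers the configured curve directly (the tests close this
  generator↔estimator loop). The defaults give M-spreads of ≈ 1.6
  near the detection floor falling to ≈ 0.35 for abundant features.
- **Biases**: one Normal(0, 0.25) log2 offset per patient × card,
  constant over time (it cancels in within-patient ratios but moves
  quantiles, which the anchoring stage corrects).
- **Effects**: planted features receive ±effect in log2, by default
  3× the local spread (`spread_multiple` mode), ramped 0.5/0.5/1 over
  the three post-baseline time points to mimic a dose titration that
  starts at a quarter dose. Effects are identical across patients by
  default; `patient_effect_sd` adds heterogeneity for robustness
  experiments. Planted features are drawn from expressed features at
  least one log2 unit above the floor — an effect on an unexpressed
  feature is unobservable by construction, and "sensitivity" would be
  meaningless for it.
- **TaqMan output**: log2 signals convert to Ct = log2(10⁹) − log2 S,
  clipped at the instrument ceiling Ct 45; censoring at 38 is left to
  preprocessing, as in the real two-stage semantics (raw Ct between 38
  and 45 exist but count as not detected).

What passing tests therefore show: the pipeline recovers effects of
the planted form (Gaussian, shared across patients, intensity-scaled)
at the stated sensitivity/FDP under realistic censoring and noise
levels. What they do not show: robustness to amplification artifacts,
probe cross-hybridization, RNA-quality batch effects, heavy-tailed or
correlated noise, or patient dropout — none of which the generator
models.

## Problem sizes

The analysis drivers use the full 651-assay card cohort and a
4,000-gene intensity cohort (array-scale feature counts add nothing to
the statistics being exercised; the mRNA arm's planted effects are set
to 4× spread, reflecting how strongly type I IFN signature transcripts
are induced). The acceptance suite runs 100 null cohorts at n_perm =
200 for the calibration band, 10,000 Monte-Carlo draws against the
576-relabeling exhaustive oracle, and 5,000-feature clouds for curve
recovery.

## Known limitations

- The exponential spread family is a modeling choice; strongly
  non-monotone spread profiles fall back to isotonic interpolation
  (flagged) rather than a richer parametric family.
- The loess dialect (snapshot-averaged cyclic pairwise, one cycle) is
  one of several defensible variants; replicate-level normalization of
  real deposited data may differ in the third decimal of CV metrics.
- Identifier harmonization between miRNA assay names and interaction
  databases is assumed done upstream; the network module matches ids
  case-insensitively but performs no aliasing.
- The permutation test addresses only the global filtered count, not
  per-feature significance or FDR.
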