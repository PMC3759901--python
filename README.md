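# maidflow

Intensity-dependent fold-change (MAID) filtering for longitudinal
miRNA/mRNA expression time courses in small patient cohorts.

## The problem

Drug-response profiling studies often measure each patient a handful of
times (here: immediately before treatment, ~48 h, ~96 h, and one month
after the first injection) on noisy platforms — TaqMan low-density
real-time PCR cards for miRNAs, expression microarrays for mRNAs. With
six patients there is little power for classical per-feature tests, and
the measurement noise of both platforms grows sharply as expression
approaches the detection limit, so a fixed fold-change cutoff either
floods the result with low-abundance noise or misses genuine changes in
abundant features. `maidflow` implements the full analysis chain for
this setting: preprocessing, intensity-adjusted fold-change filtering,
a within-patient permutation test, validation statistics, and
miRNA → mRNA target-network integration — plus a synthetic-cohort
generator with planted ground truth so every stage is testable without
any download.

## The statistic

For each patient and each post-baseline comparison, features are placed
in MA coordinates, M = log2(x_t) − log2(x_b) and
A = (log2(x_t) + log2(x_b))/2. The spread of M shrinks with A; it is
summarized by an exponential regression curve fitted to per-bin
standard deviations of M:

    f(A) = a·exp(−b·A) + c,   a, b ≥ 0, c > 0.

The **MAID score** of a feature is M / f(A) — an adjusted fold change
in units of the local noise, so low-abundance features need a larger
raw fold change to reach any fixed cutoff. A feature is *up-regulated*
in a comparison when its score exceeds C in at least k of n patients
(*down* symmetrically below −C). The study profile shipped with the
package uses C = 2 for mRNA intensities, C = 1 for the noisier miRNA
cards, and k = 4 of n = 6 patients.

Significance of the resulting count is assessed by a within-patient
temporal permutation test: each patient's time labels are rearranged
uniformly at random (1000 times by default), the entire scoring and
filtering chain is recomputed per permutation, and the empirical
p-value is the fraction of permutations with at least as many filtered
features as observed.

Preprocessing for the TaqMan cards: threshold cycles are censored at
the detection limit Ct = 38 and converted to linear signals
S = 2^(−Ct) × 10⁹ (so Ct 38 ↦ 0.004 and Ct 20 ↦ 953), systematic
between-array differences are removed by cyclic loess per patient and
card, and each patient's 95% signal quantile is anchored per card.
Single-tube assays are quantified relative to the housekeeping miRNA
hsa-miR-191-5p and scaled by 1000.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
default synthetic cohorts (6 patients × 4 time points; 651 TaqMan
assays with 50 up- and 20 down-regulated miRNAs planted at 3× the
local fold-change spread; a 4,000-gene intensity cohort with 75 up / 20
down planted):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_maid_filter.py
python analysis/04_permutation_test.py
```

prints, among other things:

```
mirna_cards (C=1.0, k=4):
      comparison  up  down  total
t48h vs baseline  34    16     50
t96h vs baseline  37    12     49
  m1 vs baseline  48    19     67
           Total  51    21     72
  planted recovery: sensitivity 0.971, false-discovery proportion 0.056
mirna_cards: observed 72, mean null 33.2, p_emp 0.0000 (0 of 1000 permutations ≥ observed)
```

Reading: at C = 1 with the 4-of-6 rule, 72 distinct miRNAs pass over
the three comparisons (51 up, 21 down); 68 of the 70 planted miRNAs are
recovered with 4 false positives. Random relabelings of each patient's
time course produce 33.2 filtered miRNAs on average — the permuted data
still contain the planted signal, which is why the null mean sits well
above the pure-null rate — and no permutation reaches the observed 72,
so the filtered set is far beyond chance. The strongest changes appear
at one month, matching the dose-titration ramp the generator plants
(half effect during the first week, full effect at one month).

`05_validation_stats.py` re-measures five candidates in a simulated
independent 12-patient single-tube cohort (paired t-tests on
housekeeping-normalized ratios; all four planted candidates confirmed
at α = 0.10, the null candidate not), reports cross-platform Spearman
concordance (ρ = 0.848 over 432 data pairs), and writes the clustering
layout whose column dendrogram cleanly separates baseline from
one-month samples. `06_target_network.py` integrates the filtered
miRNAs and genes with synthetic prediction/validation exports (5-of-10
consensus) into a directed bipartite network in SIF/GraphML form and
tallies target hubs.

A `maidflow` command-line interface mirrors these stages
(`maidflow simulate | preprocess | maid-filter | permute | validate |
cluster | network | run`); `maidflow run --config run.yaml` executes
the whole chain from one declarative config and writes a reproducible
run report.

## Layout

    src/maidflow/      library: design/matrix IO, preprocessing, MAID
                       scoring and filtering, permutation test,
                       validation stats, target network, simulator,
                       pipeline orchestration, CLI
    analysis/          numbered narrative drivers (simulate → … → network)
    tests/             pytest suite incl. end-to-end acceptance checks
    scripts/           acceptance script
    docs/methods.md    modeling and design notes
    results/           outputs of the analysis drivers (small summaries
                       are committed; regenerable matrices are not)
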