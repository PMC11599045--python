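# Methods

## Time-course summarization

A gene's response to stimulation is summarized as the area under its
expression-vs-time curve (AUC, expression·hours) over the observed grid.
Replicates are averaged per time point first, then the trapezoid rule is
applied. On complete grids the two orders (average-then-integrate vs
integrate-then-average) coincide exactly for the trapezoid rule; averaging
first also defines the behaviour when replicate counts differ by time
point, and the chosen order is recorded in the contrast output header.
The trapezoid rule is used because it is the standard quadrature that is
exact for the piecewise-linear interpolant of sampled data; no temporal
smoothing or model fitting is applied.

Contrasts are per-gene log₂ ratios of pseudocounted AUCs,
`log2((AUC_t + c)/(AUC_r + c))`. The pseudocount default is
c = 1 expression·hour: FPKM matrices contain exact zeros, and c = 1 is
negligible against typical AUCs (tens to thousands of expression·hours on
a 24 h window) while keeping the ratio finite for silent genes. Equal
AUCs give a ratio of exactly 0 for any c. Missing values are rejected at
load time rather than imputed — the AUC is undefined on gaps and no
principled fill-in rule exists for arbitrary grids.

## Seven-class categorization

With u = chronic log₂ ratio and v = acute log₂ ratio, "up" means
u (or v) > up_thr and "down" means u (or v) < −down_thr, both strict.
Defaults up_thr = down_thr = 1.0 log₂ unit (twofold): the class squares in
the motivating analyses are visual, so the cut is a conventional fold
threshold, configurable and recorded in output metadata. The quadrant
rules leave genes that move in opposite directions in the two contrasts
uncovered; such genes are assigned to the direction-specific class of the
axis with the larger |log₂ ratio| (ChH/ChL if the chronic axis dominates,
AcH/AcL if the acute one), an exact tie falls back to NC, and all of them
carry `discordant = true`. This keeps the seven labels a total partition
— required for downstream counting — while preserving auditability.
The labelling is symmetric: negating both ratios swaps H↔L labels.

Directional gene sets use a strict threshold: "more than fourfold" is
|log₂ ratio| > 2.0, so a gene at exactly fourfold is excluded. An empty
resulting set is an error by default (an empty set silently propagating
into enrichment is almost always a configuration mistake); with
`allow_empty` it is emitted empty under a recorded warning.

## Enrichment statistics

The enrichment score is the weighted Kolmogorov–Smirnov running-sum
statistic with hit increments |r|^p / N_R and miss increments
1/(N − N_H); with p = 0 it reduces to the signed classical two-sample KS
statistic between member and non-member ranks. The weight exponent
defaults to p = 1, the convention of the widely used desktop tool.
Numerical choices:

- Ranking ties are broken lexicographically by gene id, making the
  ranking and hence ES deterministic.
- When |max deviation| = |min deviation| the positive branch is taken.
  The comparison uses a 1e-12 tolerance so that the branch choice cannot
  depend on floating-point summation order.
- If every member weight is zero (all member metrics exactly 0 with
  p > 0), hit increments fall back to uniform weights (the p = 0 limit)
  rather than dividing by zero.
- A set empty after intersection with the universe, or equal to the
  universe, is an error (the miss distribution is undefined); members
  outside the universe are dropped with a warning.

The null distribution is gene-set permutation only: ES of `n_perm`
(default 1,000) random same-size sets drawn without replacement from the
universe, seeded. Phenotype permutation is out of scope. The nominal
p-value uses the add-one convention restricted to null scores sharing the
observed sign: p = (1 + #{|null_same| ≥ |ES|}) / (1 + #{null_same}), which
bounds p ≥ 1/(n_perm + 1) and avoids p = 0. If no null score shares the
observed sign, p = 1 is reported with a degeneracy flag and NES is NaN.
NES divides ES by the mean |null ES| of the matching sign; FDR q compares
|NES| to the pooled sign-matched null NES (each set's null ES normalized
by that set's own sign-matched means), takes the ratio of null and
observed exceedance fractions, clips to [0, 1], and applies a BH-style
suffix minimum over results ordered by descending |NES| within each sign
so q never decreases as |NES| decreases. In multi-set runs each set's
permutation stream is seeded from the base seed and the set's position
among the sorted set names, so results are independent of collection
order.

The ranking metric for enrichment defaults to the log₂ AUC ratio — the
same per-gene quantity the scatter and class analyses use — and is the
only metric the pipeline computes; the ranking function accepts any
contrast, so an alternative metric only requires constructing a contrast
table around it.

## Metabolome volcano

Welch's unequal-variance t-test is implemented from the closed-form
statistic and Welch–Satterthwaite degrees of freedom with the two-sided
tail from the t distribution (the scipy implementation is used only as an
independent cross-check in the tests). If both groups are constant with
equal means the result is (t = 0, p = 1) by convention; constant groups
with unequal means are an error, since the statistic is infinite.

The `significant` flag is raw p < 0.01, deliberately uncorrected: the
volcano is read against a horizontal significance line, and counting
"significant metabolites" must match that line. A Benjamini–Hochberg
q-value column is emitted for good practice but never drives the flags.
Fold changes use a pseudocount of half the smallest positive abundance in
the table (configurable) — a standard detection-limit surrogate, since no
rule for zero abundances is given for these panels. Flags decompose
significance (p only) from effect size (|log₂ FC| > log₂ fold-threshold)
so either reading of "differential" can be computed.

## Synthetic data generator

The generator emulates the three-condition LPS design: per-gene log-normal
baseline (defaults: natural-log mean 3, sd 1, i.e. median ≈ 20 FPKM), a
shared induction curve with value 1 at t = 0, linear rise to `peak_fold`
(default 8) at 4 h and exponential relaxation (rate 0.15/h) afterwards,
sampled at 0/4/8/12/24 h with 2 replicates. The field list for the
kinetics needed a peak amplitude in addition to peak time and decay rate;
`peak_fold` = 8 was chosen as a typical strong LPS induction. Class
effects multiply the CHyp and/or AHyp trajectory by 2^±effect (default
effect 2.0 log₂ units); replicate noise is multiplicative 2^N(0, sd²)
with sd 0.25 log₂ units. Log-normal levels with log-scale noise match
FPKM positivity and fold-change semantics. Defaults put 60 genes in each
directional class and 640 in NC (1,000 genes total) — large enough for
stable class-recovery and enrichment statistics, small enough that the
whole synthetic study runs in seconds.

All randomness flows from one seed through a counter-based substream per
gene (a generator keyed by (seed, gene index)), so enlarging the gene
panel never perturbs existing genes, and identical seeds give
byte-identical outputs. A second generator draws per-gene (chronic,
acute) effects from a bivariate normal with a designed correlation, for
checking that estimated AUC-ratio scatter reproduces a designed Pearson
r. The metabolome generator plants differential metabolites by shifting
one group's mean by 2^effect (default 3 log₂ units, i.e. 8-fold) inside a
null panel (default 60 metabolites, 3 samples per group).

What the generator does not emulate: library-size/normalization
artifacts, batch effects, gene–gene correlation, count noise at low
expression, heteroscedastic per-gene noise, or the detection-limit
censoring of real metabolome panels. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the designed
model, not robustness to those real-data complications.

## Sizes used in the checks

Oracle and calibration checks run at 1,000 random AUC fixtures, 500
enrichment fixtures (N ≤ 50), 2,000 permutation-calibration trials with
199 permutations over a 200-gene universe, 1,000 Welch fixtures plus a
10,000-metabolite null panel, 20 seeds for class recovery, 200 runs for
enrichment sign recovery, and 100 seeds for metabolome recovery — sizes
at which the Monte-Carlo error of each rate is well inside its acceptance
margin while the whole suite stays fast.

## Known limitations

- The AUC discards temporal shape: an early spike and a late plateau with
  equal areas are indistinguishable. This is intrinsic to the summary,
  not a defect of the implementation.
- Gene-set permutation ignores inter-gene correlation, so nominal p and
  FDR are calibrated for independent rankings; phenotype permutation,
  which preserves correlation, is deliberately out of scope.
- The discordant-gene rule is a convention; analyses sensitive to those
  genes should filter on the `discordant` flag.
- The volcano stage tests each metabolite marginally; with small panels
  and n = 3 per group the Welch test is conservative (observed type-I
  fraction ≈ 0.005 at the 0.01 line).
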