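# Methods

This note records the statistical model behind each component, the
conventions and defaults chosen where the field leaves them open, and what
the synthetic-data tests do and do not demonstrate.

## Data model and conventions

All statistics operate on a complete genes × samples matrix of
quantification cycles (Cq).  Values must be finite and inside the open
interval (0, 45) — the usual cycling range of a qPCR run; anything else is
rejected at ingestion with the offending coordinates.  Missing cells are
never imputed: all four stability statistics are built on pairwise or
groupwise spreads over samples, and silently imputing a cell would bias
every pairwise SD that touches it.  A `drop_incomplete_samples` option
removes whole sample columns instead.  Technical replicates are expected to
be pre-averaged into one Cq per biological sample.

Amplification efficiency `E` is the fold amplification per cycle
(`E = 2` is perfect doubling); entries must lie in [1.5, 2.2] and genes
without an entry default to 2.0.  Relative quantities use the standard
transform `Q(g, s) = E_g^(min_s' Cq(g, s') − Cq(g, s))`, anchoring each
gene's most abundant sample at `Q = 1` and keeping `Q ∈ (0, 1]`.  Logs are
base 2 throughout.

Delimited-text readers auto-detect tab versus comma, use '.' as the decimal
point, and refuse any malformed cell rather than constructing a partial
table.  Report writers emit shortest-round-tripping float representations,
so re-reading a report reproduces every numeric field exactly and writing
the same result twice is byte-identical.

## Candidate screen

For a vector of per-condition abundances the screen reports the arithmetic
mean, the sample coefficient of variation (n − 1 denominator) and a
dispersion measure `dpm`, implemented as the population-denominator (n)
coefficient of variation.  The published dispersion statistic this mirrors
is defined only through its software implementation; the population-CV
form reproduces its monotone use (lower = more stable gene), its scale
invariance, and its slightly-below-CV magnitude on small condition counts,
but is not guaranteed to match that tool digit for digit.  Screening
therefore also accepts precomputed mean/CV/DPM columns and uses them
verbatim, so published screen summaries can be fed through unchanged.  A
dispersion value known only to exceed a bound (a "> 0.3" table entry) is
stored as `inf`, which makes threshold filters behave correctly while
marking the value as censored.

Filters: annotation present, mean expression strictly above `min_fpkm`
(default 10), dispersion at most `max_dpm` (default 0.3, inclusive).
Unannotated genes are retained with `passes = False`, never dropped.

## geNorm

`V_jk = SD_s[log2(Q_j / Q_k)]` with the n − 1 denominator;
`M_j = mean_{k≠j} V_jk` over the genes still in play.  The gene with the
highest M is excluded stepwise down to a final pair, which shares one M
(their mutual pairwise SD).  Per-gene reported M is the value at that
gene's exclusion step, matching how stepwise geNorm output is commonly
tabulated; the full trajectory is retained.  Ties on M during exclusion
remove the lexicographically last gene — an arbitrary but deterministic
rule; ties are practically confined to constructed data.

Pairwise variation `V(n/n+1) = SD_s[log2(NF_n / NF_{n+1})]` where `NF_n`
is the geometric mean of the n most stable genes' quantities, adding genes
in reverse exclusion order.  The recommended number of references is the
smallest n with `V < 0.15`; the cutoff is a convention, not a hard rule,
and is configurable.

When every efficiency is exactly 2, `log2 Q` differences reduce to Cq
differences, so the initial (pre-exclusion) M equals the comparative ΔCt
mean pair-SD gene for gene; the test suite asserts this identity to 1e−9
and checks the whole stepwise trajectory against a deliberately naive
brute-force implementation kept in the test tree.

## NormFinder

On `y = log2 Q`, the model is `y_igj = α_ig + b_gj + ε_igj` with sample
(loading) effects `b_gj` shared across genes and `ε_igj ~ N(0, σ²_ig)`.
Within each group, residuals are double-centered (gene means and sample
means removed).  Because subtracting the per-sample mean mixes all genes'
noise, the raw residual mean squares `u_i = Σ_j r²_ij/(n_g − 1)` satisfy
`E[u_i] = (1 − 2/k) σ²_i + Σ_l σ²_l / k²`; solving this moment system
gives the unbiased estimator

    σ̂²_ig = (u_ig − Σ_l u_lg / (k (k − 1))) · k / (k − 2),

floored at zero (hence the requirement of k ≥ 3 genes).  Inter-group
deviations `d_ig` are the double-centered gene × group means; they sum to
zero over genes and over groups, so only deviations *relative to the
average gene's shift* are identifiable.  The deviations are shrunk toward
zero by the empirical-Bayes factor `γ̂²/(γ̂² + σ̂²_ig/n_g)` with
`γ̂² = Σ d²/((k−1)(G−1)) − mean(σ̂²/n)` floored at zero, so apparent group
differences explainable by sampling noise do not count against a gene.
The stability value combines both components additively,

    SV_i = mean_g ( |d̃_ig| + sqrt(σ̂²_ig / n_g) ),

which is monotone in each component and reduces to `sqrt(σ̂²_i)` in
single-group mode.  Grouped mode requires at least two samples per group;
a singleton group raises an error that points to single-group mode.
Because the exact bookkeeping of the original tool's shrinkage variance
differs between its published variants, correctness is established by
parameter recovery: on simulations with known per-gene noise and shifts,
SV rank-correlates at ~0.97 (mean over 100 seeds) with the true total
variation.

## BestKeeper

All descriptives are computed on raw Cq, not quantities.  "SD" follows the
BestKeeper convention of the *mean absolute deviation* from the arithmetic
mean (in cycles), not the root-mean-square deviation; CV is `100·SD/mean`
percent.  The index is the per-sample geometric mean of Cq across genes;
each gene is correlated against it (Pearson, two-sided p from the
t-transform with n − 2 df).  A constant gene has undefined r, reported as
NaN, and is still acceptable (SD = 0).  Genes with SD > 1 cycle are
flagged unacceptable.  The ranking key is (SD, CV, −r), ties broken by
gene identifier; published BestKeeper tables do not always order strictly
by any single key, so the composite key is a documented convention here.

## Consensus ranking

Each method contributes dense positional ranks; tied blocks share the
block's minimum position under the default `min-rank` rule (a tied best
pair is 1, 1 and the next gene 3) or the mid position under `mid-rank`.
The consensus statistic is the geometric mean of a gene's ranks across
methods, clamped into [min, max] of the inputs to guard the bounding
invariant against floating-point rounding; final ties are broken by gene
identifier and flagged.  `min-rank` is the default because it reproduces
the bundled example's published comprehensive rankings for the all-stress
and dehydration panels in full (as does mid-rank; scoring a tied pair by
listed order instead creates a spurious geomean collision between the top
two genes of the all-stress panel).  The temperature panel of the bundled
dataset is *not* reproducible from its printed per-method ranks by a
geometric mean under any tie rule — the printed consensus row there
disagrees with the geometric mean of its own inputs — so that panel is
kept as data but not asserted.

## Normalization and validation

The normalization factor of a sample is the geometric mean of the
reference genes' relative quantities; a target's normalized expression is
`Q(target, s) / NF(s)`.  With one reference and `E = 2` everywhere this is
exactly the textbook `2^−ΔΔCq`.  Fold change versus a control group is the
ratio of arithmetic group means of linear-scale normalized quantities
(deterministic and symmetric; the alternative mean-of-ratios estimator is
not).  Significance uses a two-sided Welch t-test on log2 normalized
values — a documented assumption, since small-n qPCR contrasts are
conventionally tested on the log scale without assuming equal variances;
stars mark p < 0.05 and p < 0.01.  Direction is strictly `fold > 1` = up,
`fold < 1` = down.  RNA-seq cross-validation uses plain condition-level
FPKM ratios without shrinkage, and profile concordance reports per-
condition log2 differences, their mean absolute value, and the fraction of
conditions with agreeing direction.

Two analytic properties anchor this module: a sample-wide loading offset
(a constant added to every gene's Cq in one sample) is absorbed by the
normalization factor, and on noise-free data a reference with a k-fold
group shift biases a flat target's apparent fold change by exactly 1/k —
the classic overestimation produced by normalizing against an unstable
gene.

## Synthetic data

`Cq(g, s) = baseline(g) + group_shift(g, group(s)) + sample_effect(s) +
noise(g, s)`.  Noise is additive Gaussian on the cycle scale (log-normal
multiplicative on quantities, the standard qPCR error model); sample
effects are shared across genes within a sample, encoding the premise that
multi-gene normalization factors cancel loading differences exactly.
Defaults mirror a typical abiotic-stress validation design: 9 genes, 5
treatment groups × 3 biological replicates, baselines uniform on 20–27
cycles, 0.2-cycle technical noise, 0.3-cycle sample effects, efficiencies
uniform on 1.95–2.01, and group shifts up to 2 cycles.  Designed-unstable
genes draw a shift in every non-control group with magnitude between a
quarter of `shift_max` and `shift_max` (random sign), so the ground-truth
stable/unstable labels are meaningful by construction rather than a matter
of sampling luck.

The recovery harness reruns the full four-method + consensus pipeline over
seeded replicates and reports the fraction in which all designed-stable
genes occupy the top k ranks.  Under the default design the consensus
ranking recovers the stable trio in the top 3 in ≥ 95% of 200 replicates
(the acceptance script measures this at run time).

What the simulations do **not** emulate: inter-plate calibration drift,
efficiency misestimation, amplification failure or censored Cq values,
non-Gaussian outliers, and correlated biological responses between genes.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated error model, not robustness of
reference-gene selection to every laboratory artifact.

## Problem sizes and numerics

The test suite and the acceptance script use small problem sizes chosen to
make the checks sharp and quick: 50 random tables for the geNorm/ΔCt
identity (tolerance 1e−9), 20 tables of 4–6 genes for the brute-force
oracle, 200 simulation replicates for consensus recovery, 100 seeds for
NormFinder parameter recovery, and 500 draws for the fold-change
calibration check.  Stability statistics require at least 3 samples (SDs
over fewer are degenerate) and geNorm/NormFinder at least 3 genes.
Negative variance estimates are floored at zero; geometric means are
computed in log space.
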