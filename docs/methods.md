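# Methods

This note documents the statistical models implemented in `droughtmet`,
their assumptions, the defaults that matter, and the choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Experimental design model

A sample is located by five design coordinates: genotype (wild-type Col-0,
*BRL3ox*, *quad*), tissue (shoot/root), watering regime, day (0–6) and
replicate (1–5). Day 0 is modeled as a distinct regime level, `basal`,
shared by the watered and drought series: the pre-treatment point is
sampled once per (genotype, tissue, replicate) and belongs to both series.
This avoids double-counting time 0 and makes the full factorial enumerate
to 3 × 2 × 5 × (1 + 6 + 6) = 390 samples; a root-only batch restricted to
replicates 3–5 enumerates to 117. Fresh weight (mg) is carried per sample
and is mandatory for normalization.

## Normalization

Raw GC-MS peak areas are modeled as

    peak[m, s] = concentration[m, s] · fresh_weight[s] · detector[s]

with the spiked internal standard (ribitol, a sugar alcohol absent from
plant extracts) contributing `standard_amount · detector[s]`. The two-step
normalization

    value'[m, s] = peak[m, s] / peak[standard, s] / fresh_weight[s]

therefore cancels the per-sample nuisance factors algebraically exactly
(bit-identically for power-of-two gains; to rounding error otherwise). The
standard row is consumed by the operation. Missing cells stay missing —
no imputation, no pseudo-counts; a zero or negative value at the log step
is an error that lists the offending cells rather than being patched
silently.

The log base is natural by default (configurable to 10 or 2). The base
only shifts quantile summaries by a constant factor and does not affect
which samples the outlier rule flags, which metabolites are selected, or
any correlation-based statistic.

## Outlier screen

After log transformation, the first and third quartiles (Q1, Q3) are
computed over **all pooled non-missing values** of the dataset (all tissues
together), with linear interpolation between order statistics. A sample is
flagged when its own median is strictly above Q3 or strictly below Q1; a
median exactly at a quartile is kept. Flag direction (`above_q3` /
`below_q1`) is reported per sample. No further normalization is applied
after outlier removal, and removing samples triggers a recomputation of
the "not identified in that tissue" report so that a metabolite losing its
last observation in a tissue is surfaced.

Detection margin: the rule's implicit threshold is half the pooled IQR.
With synthetic baselines spanning six decades the pooled IQR is about
three decades, so a two-decade median shift clears the threshold by only
~0.5 decade and sits near the detection boundary (quartile sampling noise
can occasionally absorb it); a three-decade shift is comfortably inside.
Real artifact shifts of one order of magnitude would **not** be separable
from a spread this wide by this rule alone — the rule's power depends on
the ratio of shift to pooled spread, not on the shift in isolation.

## Group comparisons

Two-sided pooled-variance Student's *t*-tests per metabolite, screened at
raw *p* < 0.025 by default. Sidedness is a deliberate choice documented
here: a two-sided test at 2.5% is conservative relative to a one-sided
reading of the same threshold. Benjamini–Hochberg q-values are reported in
the output for transparency but do not drive the default screen, which is
a raw-p threshold by design. Fold-changes are `log(median_B / median_A)`
on the normalized scale — medians, not means, so a single aberrant
replicate cannot flip the sign. Zero variance in both groups with equal
means yields *p* = 1 by convention. Metabolites with fewer than two
non-missing values in either group are reported as untestable, never
silently tested.

The shoot/root ratio is a paired variable: replicates are paired by
(genotype, regime, day, replicate), and a pair is dropped — and recorded —
whenever either tissue's sample was discarded by QC, since an unpaired
ratio is undefined. Ratios are reported as log-ratios, so comparing ratios
is identical to comparing differences of log tissue values.

## Differential time-course dynamics

Per metabolite, with day as a continuous covariate:

    y ~ Σ_k β_k d^k + Σ_g Σ_k γ_{g,k} d^k · 1[genotype = g],  k = 0..degree

fitted by least squares on one tissue and one series at a time (basal
day 0 belongs to both series). Two nested *F*-tests are reported: the
global test (full model vs intercept) asks whether anything depends on
time or genotype; the differential test (full model vs one shared curve)
isolates the genotype × time interaction, including genotype offsets.
Selection requires both a BH-adjusted differential q below threshold
(default 0.05) **and** R² ≥ 0.6, so significant but badly fitting profiles
are not called. Defaults: degree 2 — exponential accumulation is linear in
the log and a quadratic absorbs curvature of saturating profiles over six
days. This is a compact re-implementation of the two-step
polynomial-regression idea used by time-course omics screens (global fit,
then coefficient comparison); it does not perform stepwise variable
selection.

Selected profiles are clustered on per-day medians (replicates and
genotypes pooled), standardized per metabolite, by complete-linkage
hierarchical clustering on Euclidean distance.

## Dynamical Network Biomarkers

Before a critical transition, theory predicts a dominant group of
variables whose variance and mutual correlation rise sharply while their
correlation with the rest of the system falls. Per genotype and tissue:

1. Log abundances are standardized against the day-0 basal controls:
   z = (x − mean_ref) / sd_ref per metabolite, so "drastic increase" is
   measured relative to the control state. Metabolites with zero or
   inestimable reference SD are excluded with a record.
2. At each drought day the replicate vectors are clustered by
   complete-linkage hierarchical clustering on 1 − |Pearson r|, cut to
   `k_clusters` groups; clusters of at least `min_cluster_size` members
   (default 2 — observed DNBs can be pairs) are scored:
   SDin = mean member replicate SD, PCCin = mean absolute pairwise member
   correlation, PCCout = mean absolute member/non-member correlation, and
   CI = SDin · PCCin / PCCout (undefined, and recorded as such, when
   PCCout = 0).
3. Cluster identities are chained across days by maximal member overlap to
   give CI trajectories; the critical point is the day of the global CI
   maximum, ties broken toward the earlier day (early-warning semantics).

SDin is the mean of member SDs (not a pooled SD), and absolute correlation
is used throughout. All three statistics are estimated from the replicates
at one day, so their stability is governed by the replicate count: with
only 5 replicates the null distribution of |r| is centered near 0.6 and
complete-linkage clustering of such estimates is essentially noise — a
limitation inherent to correlation-based critical-transition detection on
small designs, not to this implementation. Recovery benchmarks in the test
suite therefore run the detector on simulations with 20 replicates per
time point, where correlations are estimable, and use `k_clusters = 15`
for a 40-metabolite panel so that forced merging does not dilute a
planted 3-member cluster; the 5-replicate study design remains the
generator default. Passing these benchmarks shows the machinery is
correct and recovers planted transitions when the data can support the
estimates; it does not imply comparable power at 5 replicates.

## Pathway integration

Per pathway and per omic layer, a one-sided upper-tail hypergeometric
(Fisher's exact) test of the overlap between the hit list and the
pathway's annotated features, against a user-supplied universe. The two
per-omic p-values are merged with Fisher's combined probability test,
X = −2 Σ ln pᵢ compared to χ² with 2k degrees of freedom. An omic with no
annotated members in a pathway enters as p = 1 (no evidence) — this
convention is what makes gene-only pathways rankable and reproduces
published combined values computed from a significant gene p-value and a
unit metabolite p-value. Duplicate identifiers are counted once. Pathway
annotation is a plain two-column mapping file; no online database access
is performed.

## Synthetic data generator

The generator emulates, per sample: log10-uniform baselines on [−3, 3]
(six decades, the heavy-tailed positive spread typical of GC-MS panels),
lognormal replicate noise with CV 0.2, fresh weights of 55 ± 5 mg (shoot)
and 30 ± 5 mg (root), and a log-uniform detector factor in [0.5, 2]
applied to every row including the standard — so normalization is
exercised, not assumed. Planted structure, recorded as ground truth:

- **Osmoprotectants** (raffinose, galactinol, proline, sucrose, galactose,
  maltose by default) accumulate as baseline · exp(rate · day) in the
  drought series only, with rates 0.3/day (WT, quad) and 0.7/day
  (*BRL3ox*) — the steeper-in-*BRL3ox* pattern; watered series are flat.
- **DNB cluster** (3 members by default): at the critical day (default 5)
  of the drought series the members' log-noise SD is multiplied by 3 and a
  shared latent factor with loading √0.8 induces pairwise correlation
  ≈ 0.8; at other days members are independent.
- **Outliers** (8 samples, alternating ±2-decade shifts): the shift is
  applied to the metabolite rows but **not** the internal-standard row —
  an artifact that scaled every row including the standard would be
  cancelled by normalization and would be invisible downstream, which is
  not what the flagged real-world artifacts look like.

What the generator does not emulate: chromatographic batch structure,
retention-index drift, missing-not-at-random censoring at the detection
limit, correlated biological pathways beyond the planted cluster, or
heteroscedastic per-metabolite noise. Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to every failure mode of real GC-MS
data.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation between order statistics.
- Correlations of zero-variance rows are treated as 0 (no association
  information), and the correlation matrix is clipped to [−1, 1] before
  taking absolute values.
- Ties in the CI maximum break toward the earliest day; cluster chain
  matching breaks overlap ties toward the older chain id, then member
  order.
- Degenerate two-group tests (zero variance both sides) return p = 1 on
  equal means, p = 0 otherwise.
- Matrix round-trips are bit-exact: floats are written with their shortest
  round-trippable representation and parsed with correctly-rounded
  conversion.
- Seeds: every stochastic routine takes an explicit seed; identical seed
  and config give byte-identical outputs.

## Problem sizes used in tests and the acceptance script

Test fixtures use the full 390-sample design with 25–60 metabolites;
calibration checks use 1,000–2,000 simulated null metabolites; DNB
recovery runs 50 seeds at 40 metabolites × 20 replicates; dynamics
recovery runs 100 seeds at 20 metabolites. These sizes make the whole
suite run in well under a minute while keeping Monte-Carlo fractions
stable at the asserted thresholds.

## Known limitations

- The DNB composite index has no significance test (none is defined for
  it); CI trajectories are descriptive and power depends strongly on
  replicate count, as discussed above.
- The quantile outlier rule assumes artifacts shift a sample's whole
  distribution; it will not catch partial, metabolite-specific corruption.
- The polynomial dynamics model treats replicates as independent
  observations; no within-replicate autocorrelation across days is
  modeled (replicates are destructive samples, not repeated measures of
  one plant, so this matches the design).
- Fisher's combination assumes the per-omic p-values are independent;
  gene- and metabolite-level evidence for the same pathway is plausibly
  positively dependent, making combined p-values mildly anti-conservative.
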