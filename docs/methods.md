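# Methods

This note documents the statistical procedures `clockpe` implements, the
defaults it chooses where the published analysis left details open, what
the synthetic cohorts do and do not emulate, and the package's known
limitations.

## Inputs and scope

The pipeline operates on already-harmonized, log2-scale gene × sample
expression matrices with complete values (TSV), per-sample phenotype
tables (condition PE / non-PE plus a preterm flag), and GMT gene-set
collections.  Upstream microarray processing — probe-to-gene collapsing,
normalization, batch correction — is out of scope; a missing expression
value is an error, never imputed, because the harmonized GSE75010 input
this pipeline targets is complete.  Gene symbols are uppercased on
ingest and matched by exact string everywhere (no alias mapping).

## Differential expression

Per gene, a two-sample two-tailed t-test of PE vs non-PE.  The default
is the pooled-variance Student test (df = n1 + n2 − 2); Welch with
Satterthwaite df is available by flag.  The published tables do not
discriminate between the two at their printed precision, and on equal
group variances they coincide.  Both are computable from (n, mean, SD)
summaries (`summary_t`), which is how the implementation is verified
against published descriptive tables: means/SDs printed at 2 decimals
reproduce printed p-values only approximately (e.g. CRY1 in the
discovery cohort gives p ≈ 0.030 against a printed 0.0250), so tests
assert closeness, not equality, there.

Multiple testing uses the Benjamini–Hochberg step-up over the candidate
list (m = the list length, 17 for the clock genes):
q(i) = min over j ≥ i of min(1, p(j)·m/j) on the sorted vector, mapped
back to input order.  Significance requires p < 0.05 AND q < 0.10.
Degenerate cases: zero variance in both groups with equal means yields
t = 0, p = 1; zero variance with unequal means yields p = 0.

Percent change is (mean_case − mean_control)/mean_control × 100 on the
log2 scale, signed (negative = down in PE), matching the convention of
the published footnote arithmetic.

The cross-cohort overlap intersects the two significant-gene sets and by
default drops genes whose direction of change disagrees between cohorts
(the reported three-gene signature — CRY1 up, NR1D2 down, PER3 down — is
concordant); `allow_discordant` retains them flagged.

## Risk score and Firth association

Up-regulated genes enter the score with a plus sign; down-regulated
genes enter as (offset − expression) with a per-gene integer offset, the
smallest integer strictly greater than the gene's maximum observed value
across all cohorts analyzed (9.0 → 10, 10.2 → 11).  This reconstruction
reproduces the published offsets (11 for NR1D2, 9 for PER3, 10 for
CLOCK) and makes every term positive and increasing in PE risk.

The score is dichotomized at its per-cohort median (never pooled across
cohorts).  Samples strictly below the median are "low", strictly above
are "high"; a sample exactly at the median is assigned to the high group
by default.  With 157 distinct scores this puts 78 samples in the low
row and 79 in the high row, matching the published contingency table;
the opposite tie rule is available as `tie="low"`.

Association uses logistic regression with Firth's Jeffreys-prior
penalty: maximize ℓ(β) + ½ log det I(β) by Newton iteration on the
modified score U*(β) = X′(y − p + h(½ − p)), h the hat-matrix diagonals,
with step-halving whenever the penalized log-likelihood would decrease.
Convergence requires max |U*| < 1e-9 (at most 25 iterations); the tight
tolerance keeps the estimate within 1e-6 relative of the analytic
benchmark below.  No covariates are included (the source cohorts'
maternal characteristics were balanced or unavailable).  On a saturated
2×2 design the Firth estimate equals the half-count-corrected odds ratio
((a+½)(d+½))/((b+½)(c+½)), which the package exposes separately
(`odds_ratio_closed_form`) and uses as an independent oracle in tests;
the penalty also keeps estimates finite under complete separation, where
unpenalized ML diverges.  Confidence intervals are Wald on the penalized
fit, exp(β ± 1.96·se); on the published tables these reproduce the
printed 95% CIs to within one unit in the second decimal.  Whether the
original analysis used Wald or profile-likelihood intervals is not
documented; both bracket the printed values and Wald is the package
default.

## Single-sample pathway scores

The GSVA statistic is implemented from scratch in three deterministic
steps.  (1) Per gene, a Gaussian-kernel smoothed empirical CDF evaluated
at each sample, z_gs = mean over k of Φ((x_gs − x_gk)/h_g), with
bandwidth h_g = sd_g / 4.  Because the bandwidth scales with the SD, the
statistic is exactly invariant to affine transforms of a gene's row, and
strictly increasing in the sample's own value.  A zero-variance gene
degenerates to the tied-ECDF limit (all samples share one value) with a
warning.  (2) Per sample, genes are ranked by decreasing z and given the
symmetric weight |N/2 − rank|, largest in both tails.  (3) Per set and
sample, a weighted Kolmogorov–Smirnov-like random walk: member positions
gain w^τ (normalized by the set's total weight, τ = 1 by default),
non-member positions lose 1/(N − |S|).  The enrichment score is the sum
of the largest positive and largest negative deviation ("diff", the
default) or the signed largest deviation ("maxdev"); either is bounded
in [−1, 1].  Sets are intersected with the matrix's genes and filtered
to 5–500 members before scoring; genes absent from the matrix are
dropped from sets silently.

These algorithmic constants (Gaussian kernel, divisor 4, τ = 1, diff
statistic, 5–500 size filter) follow the published GSVA construction and
are all exposed as parameters; bit-level equivalence with the reference
R implementation is not claimed — correctness is established against a
straight-line brute-force oracle and the boundary/symmetry properties
above.

## Pathway association

Differential pathway testing between conditions re-implements the
standard two-group empirical-Bayes moderated t: per-set pooled residual
variance s² with d = nA + nB − 2 df, prior (d0, s0²) estimated by
closed-form method of moments on log s² (matching the mean and the
excess variance of log s² over trigamma(d/2); the trigamma inverse is
solved by Newton).  The shrunken variance is s̃² = (d0·s0² + d·s²)/(d0+d)
and t̃ uses d0 + d df.  When the observed spread of log s² is no larger
than its sampling noise, d0 = ∞ and all variances shrink to the common
value (normal reference distribution); prior_df = 0 recovers the
ordinary t-test.  Exact numerical agreement with the limma package is a
non-goal — the design here has no covariates, and the limiting cases
plus hand-computed shrinkage arithmetic define correctness.

Risk-score/pathway correlation uses the **continuous** score (the
published description does not state continuous vs binarized; continuous
is the natural reading and preserves information).  Pearson r with
two-sided p from t = r√((n−2)/(1−r²)) and the Fisher-z 95% CI
tanh(atanh r ± 1.96/√(n−3)); |r| = 1 degenerates to a zero-width
interval with p = 0.  Pathways pass if p < 0.05 AND BH q < 0.10 and (in
the pipeline) are additionally required to be differential between
conditions.  Cross-cohort pathway overlap requires a concordant sign
of r.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
per gene, log2 expression is Gaussian with group-specific mean and SD,
independent across genes by default.  `table1_defaults` returns configs
whose 17 gene specs carry exactly the published per-group means/SDs of
the two cohorts (group sizes 77/80 and 96/77) and of the term subgroup
(42/31).  On top of that: null background genes (means uniform in 6–10,
SDs in 0.25–0.75 — typical post-normalization microarray ranges); planted
gene sets whose members share a common case shift expressed in SD units;
an optional equicorrelation block within each planted set (Gaussian
copula, preserving marginals); and preterm flags drawn independently of
expression unless a per-gene preterm shift is requested (used to
exercise the term-subgroup stage).  All randomness flows from an
explicit integer seed; no global state.

What the simulations do **not** emulate: gene–gene correlation beyond
the optional block (the true clock-gene covariance is unknown),
probe-level intensities, batch effects, heavy tails, or the real MSigDB
pathway collection.  Passing tests therefore demonstrate that the
pipeline recovers planted effects of the published magnitude under
Gaussian noise — not that it reproduces the published pathway lists,
which would require the real cohort matrices and gene sets.  One
consequence quantified in the test suite: at the published effect sizes,
PER3 is recovered in the cross-cohort overlap essentially always, but
NR1D2's replication-cohort effect (d ≈ 0.45, pooled-t power ≈ 0.8) makes
its recovery frequent rather than certain, and CRY1 (d ≈ 0.35 in both
cohorts) is recovered in only a minority of paired simulations.  The
published three-gene signature is a single realized outcome, not a
near-certain event under these effect sizes.

## Pipeline, determinism, problem sizes

Stage order is fixed: differential expression before scoring, scoring
before pathway association.  Every output table carries a header with a
hash of the analysis configuration (the output directory is excluded
from the hash) and the seed; reruns with the same config and seed are
byte-identical.  Errors abort with the failing stage's name.  The
default synthetic pipeline uses the 17 candidate genes plus ~100–150
background genes and ~20 gene sets per cohort, which keeps a full
two-cohort run under a second while leaving every stage non-trivially
populated; the heavier simulation checks (500-replicate power recovery,
1,000-table Firth/BH cross-checks) run in about a minute in the test
suite.

## Known limitations

- Exact reproduction of the published pathway tables is out of reach by
  design (requires the real GSE75010 matrices and the MSigDB c2.cp
  collection); the package verifies everything that is desk-computable
  from printed numbers and replaces the rest with oracle and property
  tests.
- One printed FDR cell (NR1D1, discovery cohort) disagrees with BH on
  the printed p-values by 0.001 and is treated as a transcription slip.
- The moderated-t stage is a two-group re-implementation, not a general
  linear-model engine; no covariate adjustment anywhere (by design,
  matching the source analysis).
- Preterm information exists for only one real cohort, so the term
  subgroup applies to single cohorts; no cross-cohort term overlap.
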