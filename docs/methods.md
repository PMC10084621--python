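# Methods

This note records the statistical models the package implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Trait preparation

Growth rates are plain ratios: GRM = mass/development time (mg/day), GRH =
head width/development time (mm/day); a development time of zero is an
error. Transforms follow the conventions of the motivating experiment:
log for head width and wing pad length, arcsine for the two growth rates,
none for mass and development time. The arcsine is applied to the raw ratio,
which must lie in [0, 1] (an out-of-range value raises with the row index
and a rescaling hint). We deliberately use arcsin(x), not the
variance-stabilizing arcsin(√x); the field reports both under the same name
and the choice is recorded here so users can substitute their own transform
map in `TraitConfig`.

The collinearity screen computes all pairwise Spearman rank correlations,
then repeatedly drops one trait while any off-diagonal |r| exceeds the
threshold (default 0.9, strict inequality; at a threshold of exactly 1.0 the
rule becomes ≥ with a 1e−9 tolerance, because rank correlations of
duplicated columns come back a few ulp under 1). The victim is chosen among
the traits involved in at least one offending pair — dropping an uninvolved
trait would be nonsensical — as the one with the largest mean |r| against
all remaining traits, ties broken alphabetically. This rule is deterministic
and column-order independent; on data with the structure of the motivating
study it removes GRH, which is nearly collinear with development time and
GRM.

## Canonical correlation analysis

Both sets are standardized (mean 0, sd 1, ddof = 1). The canonical
correlations are the singular values of Σxx^(−1/2) Σxy Σyy^(−1/2); weights
are back-transformed through the inverse square roots, so canonical scores
have exactly unit sample variance and successive score vectors within a set
are uncorrelated. Rank deficiency is detected on the eigenvalues of the
within-set correlation matrix and the error names the most-involved column.

Environment factors are coded high→0/central→1, 20 °C→0/24 °C→1,
absent→0/present→1, and the coding is stored in the result. Canonical
correlations are invariant to any invertible recoding; loading signs are
not, so each axis is oriented with the largest-magnitude environment weight
positive. Published loadings may therefore differ from ours by whole-axis
sign flips; comparisons should use absolute values or flip-normalize.

Loadings are corr(variable, own-set scores); cross-loadings
corr(variable, other-set scores), which equals loading × ρ (an identity the
tests verify to 1e−10). Loadings with |value| > 0.30 (strict) are flagged,
the conventional cutoff for N > 200.

The Wilks ladder tests correlations k…m jointly: Λ_k = Π_{i≥k}(1−ρ_i²),
with p′ = p−k+1, q′ = q−k+1,

    s   = sqrt((p′²q′²−4)/(p′²+q′²−5))   (s = 1 when p′q′ ≤ 3 or the
                                          denominator is 0)
    t   = (N−1) − (p+q+1)/2
    df1 = p′q′,  df2 = s·t − p′q′/2 + 1
    F   = ((1−Λ^(1/s))/Λ^(1/s)) · (df2/df1)

t is computed from the *original* p and q at every rung, with p′, q′
entering only s and df1. This matches the asymptotic-test convention of the
standard implementations: at N = 272, p = 5, q = 3 it yields denominator
df 729.2, 530, 266 for the three rungs. df2 is stored unrounded and rounded
only for display. At p = q = 1 the rung reduces exactly to the classical
correlation F-test. A permutation experiment (n = 40, p = q = 2, 2000
permutations) confirms the analytic first-rung p tracks the permutation p
within 0.05 under the null.

## Extreme-score contrasts and candidate genes

For each analyzed axis, the n_tail = 10 highest- and 10 lowest-scoring
individuals on CCp form one two-group contrast and likewise for CCe
(an individual may appear in both contrasts; no exclusion is applied). Ties
at a tail boundary are broken by ascending individual id, making selection
deterministic. Positive log-fold-change means higher expression in the
high-score group. A gene is an axis candidate if significant at the FDR
threshold in both contrasts with the same logFC sign; genes significant with
opposite signs are excluded and reported separately.

Both contrasts of an axis must share one gene universe for the intersection
to be well defined, so the pipeline applies the expression filter once to
the pooled tail samples (CPM > 1 in ≥ n_tail samples) before either test.

## Differential expression

The DE stage is the classic exact-test route for simple two-group designs
(the quasi-likelihood GLM route is out of scope: every contrast here is a
plain two-group comparison).

* **TMM normalization.** Reference sample = upper-quartile CPM closest to
  the mean upper quartile; M/A values over genes nonzero in both sample and
  reference; 30% two-sided trim on M and 5% on A; factor = 2^(precision-
  weighted mean M) with delta-method weights; factors rescaled to geometric
  mean 1.
* **Pseudo-counts.** Counts are rescaled to the geometric mean of the
  effective library sizes. Per-sample values are rounded to integers for
  dispersion estimation; for the exact test the group *sums* are rounded
  (and left exact for logFC), which keeps logFC invariant under uniform
  depth changes to well under 0.01.
* **Dispersion.** φ_common maximizes the summed per-gene NB conditional
  log-likelihood (conditioning on group sums of the equalized counts);
  tagwise φ_g maximizes the per-gene likelihood plus prior_df (default 10)
  times the per-gene average common profile — weighted-likelihood shrinkage
  whose prior_df → ∞ limit collapses every gene to φ_common. Optimization is
  a 61-point grid on log φ ∈ [1e−4, 10] with parabolic refinement around the
  maximum; on 2000-gene matrices this is accurate to the third decimal in
  recovery experiments (true φ = 0.2 estimated 0.20; Poisson data estimated
  at the 1e−4 boundary).
* **Exact test.** Conditional on the total of the two group sums, with the
  pooled per-sample mean and group-sum dispersions φ/n_g; two-sided p sums
  the probabilities of all outcomes no more likely than the observed one
  (minimum-likelihood method, standard for conditional exact tests; a
  1e−10 relative tolerance guards the equal-probability boundary).
  The implementation enumerates the full conditional law; tests verify it
  against an independent log-gamma enumeration to 1e−10 and its null
  calibration empirically (type-I error ≈ 0.04–0.05 at nominal 0.05,
  p-values near-uniform by KS).
* **logFC** uses a small prior of 0.125 per sample per million reads of the
  common library, so it is defined for zero counts and depth-invariant.
* **FDR** is Benjamini–Hochberg over all tested genes.

No attempt is made at bit-compatibility with any particular released tool;
correctness is defined by the enumeration oracle and the calibration/power
experiments.

## Annotation transfer, enrichment, categorization

A target gene inherits a GO set S when ≥ 3 distinct reference species carry
a gene whose normalized name (lowercase, punctuation stripped, trailing
"-like" removed) matches and whose GO set equals S exactly. "Similar
function" is not used as a criterion — similarity of free-text function
descriptions is unquantifiable and irreproducible; name identity after
normalization is the operational rule. If several sets reach the species
threshold the best-supported one wins (ties broken on the sorted set
representation for determinism).

Only `is_a` edges are read from the OBO (part_of and regulates are ignored
— the conservative default); obsolete terms are dropped; annotation entries
naming unknown terms are dropped with a logged warning rather than erroring,
since public mappings routinely lag the ontology release. Annotations are
propagated to all `is_a` ancestors (true-path rule, idempotent).

Enrichment is hypergeometric upper-tail per term, per namespace, with the
background restricted to *annotated* genes of the namespace (unannotated
genes carry no information and would only dilute the universe; the
background is configurable). Terms need K ≥ 3 background genes and k ≥ 1
candidate genes; BH is applied within namespace. Categorization counts genes
at the terms exactly `level` = 2 shortest-path steps below the namespace
root, with multi-membership allowed.

## Synthetic data: what it emulates, and what it does not

The design generator reproduces the factorial structure: 2 latitudes × 2
ponds × 10 maternal lines × 2 temperatures × 2 predator levels, with a
second phenotyped larva per container with probability 0.7 — expected
N = 160·1.7 = 272, the scale of the motivating study.

Two phenotype models exist. The effects model draws Gaussian traits on their
model scale (log for head/wing) with treatment effects, interactions,
pond/family random effects, and Poisson development time on the log scale.
The planted-axis model whitens the coded environment into axes u_k, sets
t_k = ρ_k u_k + sqrt(1−ρ_k²) ε_k, and builds the analysis-scale traits so
each t_k has a linear carrier (development time for t1, log head width for
t2, log wing pad for t3, plus a noisy GRM blend of t1); mass = GRM ×
development time, so the growth rate round-trips exactly through the
pipeline's derivation. The population canonical correlations are then
exactly ρ (default 0.85, 0.5, 0.25); ρ = 0 gives a fully null phenotype
set. Development-time rounding dilutes the first correlation by under 1%.

Counts are NB with mean L_i·exp(b_g + γ_g·z_i) and gene dispersion φ_g:
log-normal relative abundances, log-normal dispersions (median 0.1,
σ = 0.5 — the typical bulk RNA-seq range), log-normal library sizes
(median 10⁶ by default; the test and acceptance profiles use 10⁴, which
keeps a full pipeline run near a second without changing any calibration
conclusion). The expression axes z_k = (u_k + t_k)/√(2(1+ρ_k)) blend
environment and traits; this link is what makes the CCp- and CCe-tail DEG
lists overlap for planted genes, mirroring the logic of the candidate rule.
Effect genes get γ = ±1.5 (natural-log units per unit z).

Not emulated: sequence content and read-level noise, sex chromosomes (all
genes are labelled autosomal — the sex-chromosome drop set is exercised on
hand-built fixtures instead), batch effects, GC/length biases, and
correlated gene modules. Passing tests therefore demonstrate the statistical
machinery under its own model assumptions, not robustness to those
real-data artifacts.

Because there is no universal sex-chromosome label, the chromosome drop set
is a mandatory explicit field whenever counts are read from disk — never a
default.

## Pipeline determinism and problem sizes

All randomness flows from one root seed through named FNV-hash substreams
(design, phenotypes, truth, counts, ontology), each below 2³¹. Reruns with
the same config and seed produce byte-identical artifacts; the run report
deliberately records no wall-clock timestamps for this reason. Axes proceed
to the expression stage when their ladder p < 0.05 (configurable; an
explicit axis list can override the gate, which the null-calibration
experiments use so that the DE stage is actually exercised when no axis is
truly significant).

Simulation sizes used by the test suite and `scripts/acceptance.py`:
parameter recovery averages 50 seeds at N ≈ 272; DE calibration uses 2000
genes at 10 vs 10 (φ = 0.2, mean 100); the end-to-end null runs 20 seeds and
the planted recovery 10 seeds at 2000 genes, library median 10⁴. These
choices keep the full suite under a minute of simulation time per section
while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Univariate GLMMs (per-trait mixed models), read mapping/counting, and
  survival analysis are out of scope.
* The exact test assumes exchangeable samples after library equalization;
  strong within-group structure (batch, family) is not modelled.
* The transfer rule's exact-set-match requirement is conservative: a single
  curation difference in one species removes that species' support.
* Enrichment treats genes as exchangeable units; no gene-length or
  expression-level bias correction is applied.
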