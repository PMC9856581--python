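# Methods

This note records the models, conventions and numerical choices behind
`immunoaging`, and what the synthetic-data generator does and does not
emulate.

## Pathway scoring

ssGSEA scores one gene set per sample from the within-sample expression
ranking. Genes are ordered by decreasing expression; the order among tied
values is fixed by gene symbol (ascending), and tied values receive average
rank values, so scoring is deterministic and independent of input row
order. The enrichment score is the sum over all gene positions of the
in-set weighted ECDF (weights `rank^alpha`) minus the out-of-set uniform
ECDF. Consequences worth knowing:

- The score depends only on within-sample ranks: any strictly increasing
  transform of a sample's expression (library-size rescaling, log, etc.)
  leaves it unchanged.
- With `alpha = 0` the score of a set is exactly minus the score of its
  complement.
- Scoring is relative within a sample: raising one pathway's genes pushes
  other pathways down the ranking, so unshifted pathways in a cohort with
  one strongly shifted pathway drift mildly below an AUC of 0.5 in response
  evaluation. This is a property of single-sample enrichment, not a bug.

`alpha` defaults to 0.25, the conventional ssGSEA weighting exponent; it is
exposed everywhere. Gene-set members absent from the matrix are dropped
with a logged warning (they are not treated as zero-expressed); a set with
fewer than two present genes, or covering the whole universe, is an error,
as is an all-constant sample (no ranking exists).

MinMax normalization maps each pathway's scores to [0, 1] across the
analyzed cohort and stores the extrema. It is idempotent, and the cohort it
is applied over matters: the default pipeline normalizes per cancer type
(`minmax_normalize_per_group`), with a single global cohort available via
`minmax_normalize`. A pathway with zero score range is an error naming the
pathway.

## Dysregulation

Tumor-vs-normal differences of pathway scores are tested per cancer with an
ordinary pooled-variance two-sample t-test and BH adjustment across the
pathway universe; significance at adjusted p < 0.05. The age model is a
simple OLS of score on age in years, significant at raw p < 0.05 — an
intentional asymmetry: the age analysis is treated as exploratory.
Empirical-Bayes variance moderation is deliberately not used; with a
pathway universe of ~17 there is little information to pool, and plain OLS
keeps the inference transparent. The tumor model carries no covariates.

Ages: tumor samples contribute their recorded age in years; normal samples
emulate donors known only by decade bracket and enter at the bracket
midpoint (lo + hi + 1)/2 — 25 for 20–29 — via `model_ages`. The age model
uses tumor samples only by default; `include_normals` adds bracket-midpoint
normals.

Overlap of the tumor- and age-significant pathway sets is a two-sided
Fisher exact test on the 2×2 membership table over the pathway universe.
Direction-aware modes keep one cell per pathway: mode `same-direction`
removes discordant pathways (significant in both but with opposite signs)
from the age set before building the table, `opposite` removes concordant
ones; concordant/discordant counts are always reported. The odds ratio is
unsmoothed (ad/bc, may be 0 or infinite); for heatmap-style output the
log2 odds ratio is capped at ±10.

The association between pathway scores and benchmark aging gene-set scores
is Spearman's rho (t-approximation p) plus a plug-in mutual-information
estimate in bits after equal-frequency discretization (default 10 bins;
ties split deterministically by input order via a stable argsort). The MI
estimator is simple and deterministic; it is biased upward at small n
(about `(bins−1)²/(2n ln 2)` bits under independence) and is meant for
ranking associations, not unbiased estimation.

## Mutation genomics

Nonsynonymous variant classes are the conventional MAF-tool default:
Missense_Mutation, Nonsense_Mutation, Nonstop_Mutation, Splice_Site,
Translation_Start_Site, Frame_Shift_Del/Ins, In_Frame_Del/Ins. Alteration
flags use "at least one nonsynonymous variant in a pathway gene"
(`include_silent` exposes the permissive alternative), so duplicate MAF
rows do not change flags but do change TMB, which counts variants. TMB is
a plain count by default and divides by a 38 Mb capture size when
`per_mb=True`.

The age–alteration logistic regression is fitted by Newton/IRLS with
step-halving (log-likelihood provably non-decreasing per iteration,
recorded in `loglik_path`), gradient tolerance 1e-8, at most 25 iterations.
Age is in years; cancer type is one-hot encoded against the first
(lexicographic) level. Perfect separation — fitted probabilities
reproducing the outcomes exactly — is reported as a non-converged fit with
a warning and the estimates returned as-is; Wald standard errors come from
the observed information at the final iterate.

Score–TMB association is Spearman by default (matching the rank-based
spirit of the rest of the package); an OLS slope is available via
`method="ols"` because burden–score relations are sometimes reported on the
linear scale.

## Network prioritization

Gene-level fold changes are computed on log2(TPM+1): FC1 = 2^(tumor − normal
mean difference), FC2 = 2^(old − young mean difference) with old defined as
age at or above the cohort median; the gene universe is restricted to genes
passing both significance filters (same tests and thresholds as the
pathway-level analyses, applied per gene). Rank product ranks |log2 FC|
magnitudes — the method prioritizes strength of joint dysregulation, not
its direction — with average ranks for ties, and orders by ascending
product with lexicographic tie-break, so output is a deterministic function
of the input set.

The propagation operator uses the column-normalized adjacency
W_ij = A_ij/deg(j) restricted to the largest connected component (excluded
nodes are reported); a raw adjacency would not converge to a probability
vector. The restart vector is normalized to sum 1 over the seeds; seeding
with raw ones merely rescales the stationary vector by the seed count and
leaves every ranking unchanged (asserted in tests). The restart probability
defaults to γ = 0.7, a conventional value that keeps roughly the
seed-neighborhood scale of smoothing; it is exposed everywhere.
Convergence is an L1 change below 1e-10 (a contraction with factor 1−γ, so
this takes tens of iterations); probability mass is conserved to 1e-12 at
every iterate and tracked. `rwr_exact` solves the stationary linear system
directly and serves as the oracle in tests.

Top-set extraction takes the top ceil(fraction · n) genes (descending
probability, ties to the lexicographically smaller symbol). Per-cancer
top-1% sets are intersected strictly by default; `min_conditions=k` relaxes
to membership in at least k sets. Seed genes are not excluded from top
sets — they carry restart mass and legitimately dominate the final
ranking. Final percentiles are rank/n.

A sizing consequence to keep in mind when interpreting recovery numbers:
the final candidate list holds ceil(0.01 · n_network) genes, so with the
default study conditions (2,000-node network, 40 planted drivers) it has 20
slots and can contain at most half of the drivers. In the shipped
end-to-end runs the pipeline routinely fills all 20 slots with planted
drivers — the ceiling, 50% recovery — across simulation seeds.

## Response evaluation

AUC is computed as the normalized Mann–Whitney U from average ranks, which
equals the pairwise responder-beats-non-responder count with ties worth one
half. The rank-sum test defaults to the two-sided normal approximation with
tie and continuity corrections; `exact=True` enumerates all group
assignments and is the right choice for the cohort sizes where the
approximation is coarsest (total n around 10 or below, where the
approximate two-sided p can deviate from the exact one by up to ~0.09 at
extreme statistics for groups of two). Multi-category responses get all
pairwise tests with BH adjustment. The discrimination flag is strict:
AUC > 0.7.

## Synthetic data

The generator emulates the statistical skeleton of a pan-cancer study on
the log2(TPM+1) scale: per-gene Gaussian baselines (mean 3, sd 1.5), a
per-cancer Gaussian offset (sd 0.3) giving cancer-specific profiles,
planted tumor effects (±2 log2 units), planted linear age trends (±0.03
log2 units/year centred at age 50), Gaussian noise (sd 1), back-transform
`2^x − 1` clipped at zero. Ages are uniform integers 20–89 bracketed by
decade. Driver genes carry the tumor effect, the age effect and a planted
all-pairs clique inside a preferential-attachment (scale-free) network, so
end-to-end recovery is well-posed; non-driver planted genes carry exactly
one effect. Effect signs are random per gene, matching the mixed up/down
dysregulation seen in real cohorts. MAF simulation assigns
Poisson-distributed nonsynonymous variants to uniform genes with ~10%
silent rows to exercise the filter. Response cohorts shift one pathway's
genes by a chosen log2 amount in responders.

Default sizes — 2,000 genes, 3 cancers, 80 tumor + 80 normal samples per
cancer, 200 tumor-planted and 200 age-planted genes containing 40 shared
drivers, a 2,000-node network with attachment 3, 17 pathways of 60 genes —
are the package's reference study conditions: large enough that the planted
effects are comfortably detectable by the stated tests, small enough to run
in seconds. What the generator does *not* emulate: batch effects, copy
number, tissue composition of real normals, correlated gene modules beyond
the planted ones, mutation hotspots, or hypermutators. Passing tests
demonstrate that the methods recover the structure they assume, not that
real cohorts satisfy those assumptions.

Determinism: one integer seed drives everything through
`numpy.random.default_rng`; identical configurations give byte-identical
outputs, and truth lists record every planted gene.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
whole suite completes in well under a minute of compute per heavy check: 50
random graphs up to 200 nodes for propagation-vs-closed-form agreement,
1,000 random p-vectors for BH, all ~8,000 2×2 tables with margins ≤ 12 for
Fisher, exhaustive enumeration of every achievable rank-sum statistic for
group sizes totalling ≤ 10, 500 random vectors for AUC, logistic fits at
n = 2,000 with 100 null replicates, ten end-to-end pipeline replicates at
the reference study conditions, and 50+50 response cohorts of 50/50
samples.

## Known limitations

- The normal-approximation rank-sum p is coarse for tiny cohorts (see
  above); use `exact=True` there.
- The MI estimate is a biased plug-in value intended for comparison, not
  estimation.
- The logistic model's Wald inference is unreliable under separation; the
  fit says so rather than silently returning huge z-scores.
- The two-stage pipeline's candidate-set size is fixed by the top-fraction
  rule, which bounds achievable driver recall when the planted module is
  larger than the candidate list (see Network prioritization).
- Pathway-level tumor/age detection depends on the net direction of member
  genes; a pathway whose planted genes shift in balanced opposite
  directions can be genuinely null at the pathway level even though every
  member is dysregulated.
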