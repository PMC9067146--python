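# Methods

## Statistical model

The core procedure is a two-group empirical permutation test on log-scale
abundance matrices. For feature *g* with treated values *x*ₐ and control
values *x*_b (log₂ scale), the observed statistics are the mean difference
(reported as the log₂ fold-change, since the data are already logged) and
the Welch unequal-variance t. Welch rather than pooled-variance t is used
because three-replicate omics groups frequently have unequal spread;
under the permutation null the choice is inconsequential (labels are
exchangeable either way), but Welch is the safer default for the observed
statistic.

The null is built by relabeling samples across the union of both groups,
preserving group sizes, and recomputing t and the fold-change per feature.
When the number of distinct label assignments is at most the requested
permutation count (e.g. C(6,3) = 20 for a 3-vs-3 design) every assignment
is enumerated exactly once and the null is flagged exhaustive; otherwise
assignments are sampled uniformly with replacement — a small design cannot
yield 1000 distinct relabelings, so repeats are inherent to the sampled
mode. All permuted values are pooled **across features** into a single
null; this pooling is what makes per-feature p-values with only 20
relabelings usable (the effective null size is features × assignments),
and it is the sense in which the p-values are "adjusted". No further
multiple-testing correction is applied to the thresholded p; a
Benjamini–Hochberg column is emitted alongside for inspection.

Empirical p-values are two-sided via |t| with add-one smoothing,
p = (1 + #{|t_null| ≥ |t_obs|}) / (1 + N_null), so p ∈ (0, 1] and the
sampled and exhaustive modes agree in the limit.

### Degenerate inputs

When both groups have zero variance, t is 0 if the means agree and a
documented sentinel (±10⁹, larger than any finite null value) otherwise,
so constant-but-shifted features rank most extreme instead of producing
NaN. Ties in the gap statistic's group-mean comparison take group a as the
higher group.

## Derived cutoffs

* **Fold-change cutoff** (protein and cohort presets): the mean of the
  *magnitudes* of the 2.5th and 97.5th percentiles of the pooled null
  log₂FC distribution, (|q₂.₅| + |q₉₇.₅|)/2. The signed mean of a
  near-symmetric null would be ≈ 0 and useless as a threshold; the
  magnitude mean equals the upper percentile for a symmetric null and is
  invariant under sign flips. Percentiles use linear interpolation between
  order statistics throughout the package (the convention is recorded in
  cutoff provenance because it affects bit-level reproducibility).
* **Gap cutoff**: the mean of the 25th and 75th percentiles of the gap
  values of the features already passing the p and fold-change thresholds
  (stage 1). The default uses |gap| both for deriving the cutoff and for
  the stage-2 filter; a signed mode (`gap_signed`) instead demands
  positive separation of the replicate ranges. The absolute reading is the
  default because the gap is conventionally quoted as an absolute
  difference; the signed variant is stricter and is exposed for users who
  want complete range separation.
* **Dice cutoff**: the 95th percentile of the Sørensen–Dice coefficients
  over all candidate term pairs (those sharing ≥ 3 members), computed per
  direction — the up- and down-networks have different similarity
  distributions, which is why a single study can print two different
  cutoffs (e.g. 0.56 and 0.32). A fixed cutoff can be supplied instead.

## Calling rules (presets)

| preset | p cutoff | FC cutoff | gap stage |
|---|---|---|---|
| `deg` | 0.05 | fixed 0.58 (1.5-fold) | none |
| `dep` | 0.2 | null-derived | quartile-mean |
| `cohort` | 0.05 | null-derived | none |

All inequalities are strict (p < cutoff, |log₂FC| > cutoff, |gap| >
cutoff); a feature exactly at a threshold is not called. Up/down follows
the sign of the observed log₂FC. The stage-2 (gap) set is a subset of the
stage-1 set by construction.

## Preprocessing

FPKM-scale matrices are filtered for expression — either "≥ threshold in
every sample" (`all_min`, the cell-line rule) or "> threshold in strictly
more than half the samples" (`majority`, the cohort rule); the two
inequalities are kept distinct deliberately — then transformed to
log₂(FPKM + 1) and quantile-normalized. Quantile normalization maps each
column's rank to the across-sample mean of that rank's order statistics;
tied values receive the mean of the reference values spanning their rank
range (classical convention). Normalization is applied jointly across all
samples of a comparison (not per group): joint scope is required for the
permutation null to be exchangeable. Within the bundled pipeline it is
applied per cell type, i.e. per comparison.

## Enrichment and networks

The EASE score is the hypergeometric upper tail with one overlapping gene
removed: P(X ≥ k−1) for X ~ Hypergeom(N, K, n), with p = 1 for k ≤ 1.
It is provably no smaller than the plain upper tail, making single-gene
overlaps never significant. The background universe is the set of features
passing the expressed filter, not the whole genome — the defensible choice
when the annotation source's internal background is unavailable — and term
member sets are intersected with it before testing. Enrichment p-values
are thresholded raw at 0.05 (no correction), matching how such process
lists are conventionally screened.

For the term network, each term's member set defaults to the analyzed
list's members of that term ("list" universe): the association between two
enriched terms is evidenced by the differential genes they share, not by
their full annotation overlap. The full-term universe is available as an
option. Communities come from greedy modularity maximization
(networkx), which is deterministic for a fixed graph; it stands in for the
interactive GLay community clustering of network-visualization tools,
which has no formal specification — communities here are a grouping aid,
not a quantitative claim. Each community is labelled with the majority
level-1 module of its terms, ties broken lexicographically.

Pathway attribute mapping follows the convention of multi-cell-type
network figures: node colour is the log₂FC of maximal magnitude across
cell types with its sign retained (`absmax`; a plain signed maximum would
hide strong downregulation, but it is available as `signed_max` since
either reading of "maximum fold-change" is defensible), and label-size
class counts the cell types calling the gene differential (3 → large,
2 → middle, 1 → small, 0 → non-DE). Overlap percentages round
half-away-from-zero, matching how such percentages are conventionally
printed (216/535 → 40.4%).

## Synthetic data

The generators emulate the *design* of a three-cell-line
treated-vs-control study, not any real dataset's distributions. Control
FPKM values are log-normal (normal on log₂ with baseline mean 5 and sd
1.5, i.e. typical moderately-expressed genes); treated values shift the
planted features by ±effect_log2fc (default 1.0, a 2-fold change);
replicate noise is normal on log₂ with sd 0.25 — a conventional
replicate CV for cultured-cell RNA-seq, chosen once as a realistic
default since replicate variance is rarely reported. 20% of features are
forced below the FPKM = 1 filter so preprocessing has work to do. The
proteome generator uses tighter noise (sd 0.18) and smaller effects
(0.5), sized so the null-derived fold-change cutoff lands near the
0.26–0.33 range familiar from three-replicate TMT comparisons; a
`coupling` fraction of its planted effects is copied from a paired
transcript truth table to emulate partial mRNA/protein concordance. The
cohort generator produces one large unbalanced two-group comparison
(default 20 vs 80, configurable up to hundreds per group). The annotation
generator guarantees every term a same-module partner sharing ≥ 3 members
(so the shared-members edge rule is reachable) and can oversample
designated feature sets in alternate terms to plant enrichment signal.

One global seed fans out to fixed per-generator substreams, so adding a
generator never perturbs existing fixtures; every generator is a pure
function of design + seed.

What passing tests on these data do **not** show: robustness to
count-specific mean–variance relationships, batch effects, missing TMT
channels, annotation redundancy of real ontologies, or the
library-size/length biases of real FPKM — none of which the generators
simulate.

## Problem sizes

Default simulations use 300–2000 features, 1000 permutations and ≤ 10
seeds per property; with the vectorized permutation kernel a full
pipeline run at these sizes completes in well under a minute, which is the
scale at which the package's guarantees are asserted. All sizes are
configurable upward (the design mirrors studies with ~20 000 genes and
~9 000 proteins).

## Known limitations

* The permutation null for a 3-vs-3 design has only 20 distinct
  relabelings; per-feature resolution comes entirely from pooling across
  features, which assumes features are largely exchangeable under the
  null. Features with wildly heteroskedastic noise violate this.
* "Manual inspection" steps of real analyst workflows are not modelled.
* The gap filter's two readings (absolute vs signed) genuinely differ on
  features with overlapping ranges; both are exposed, the absolute one is
  the default.
* No count-model alternatives (negative binomial), covariates, paired
  designs or multi-group comparisons.
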