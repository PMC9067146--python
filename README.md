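# permomics

Permutation-null differential analysis and process-level network inference
for two-group multi-omics designs.

## The problem

Small-replicate omics comparisons (e.g. three treated vs three control
cultures per cell line, profiled by RNA-seq and TMT proteomics) cannot rely
on parametric t-test p-values: with n = 3 per group the t reference
distribution is a poor guide and per-feature variance estimates are noisy.
A robust alternative is the *empirical permutation t-test*: relabel the
samples, recompute the Welch statistic

t = (x̄ₐ − x̄_b) / √(sₐ²/nₐ + s_b²/n_b)

for every feature under every relabeling, pool the permuted statistics
across features into one empirical null, and rank each observed |t| against
it:

p = (1 + #{|t_null| ≥ |t_obs|}) / (1 + N_null).

The same pooled null yields a data-derived fold-change cutoff — the mean of
the magnitudes of its 2.5th and 97.5th percentile log₂ fold-changes — so
the effect-size threshold adapts to the platform's replicate noise instead
of being fixed a priori. For protein data, a second-stage **gap** filter
(min of the higher-mean group − max of the lower-mean group, thresholded at
the mean of the 25th/75th percentiles of the selected features' gaps)
removes calls whose replicate ranges still overlap.

Downstream, differential lists are interpreted at the process level:
EASE-score gene-set enrichment (the hypergeometric upper tail with one
overlapping gene removed, a conservative variant of Fisher's test),
a term-association network connecting enriched terms that share ≥ 3 genes
with Sørensen–Dice coefficient 2|Pᵢ∩Pⱼ|/(|Pᵢ|+|Pⱼ|) above the 95th
percentile of the candidate-pair distribution, community clustering into
level-1 modules, cross-omics overlap arithmetic, and attribute mapping onto
user-supplied pathway networks (node colour = strongest log₂FC across cell
types; label size = number of cell types calling the gene differential).

A synthetic-data module generates matrices with *planted* effects and
ground-truth tables emulating a 3-cell-type × {control, treated} × 3-replicate
design (plus a large unbalanced cohort mode), so the whole chain is testable
without any downloads.

## Worked example

```python
import permomics as pm

design = pm.SimDesign(n_features=1000, n_cell_types=1, frac_up=0.05,
                      frac_down=0.05, effect_log2fc=1.0, noise_sd=0.25, seed=7)
matrix, truth = pm.generate_expression(design)
norm = pm.quantile_normalize(pm.log_transform(pm.filter_expressed(matrix)))
spec = pm.ComparisonSpec(group_a=norm.samples_where(condition="treated"),
                         group_b=norm.samples_where(condition="control"),
                         n_permutations=1000, seed=7)
stats, cutoffs, null = pm.run_comparison(norm, spec, preset="deg")
```

Running `python examples/01_permutation_differential_expression.py` prints:

```
expressed features: 800 of 1000
null: 20 label assignments (exhaustive), 16000 pooled t values
calls: 35 up, 42 down at p<0.05, |log2FC|>0.58
sensitivity on planted effects: 0.87
```

800 of 1000 features pass the FPKM ≥ 1 filter (the design leaves 20%
unexpressed); a 3-vs-3 design has only C(6,3) = 20 distinct relabelings, so
the null is enumerated exactly rather than sampled; 77 features pass
p < 0.05 and |log₂FC| > 0.58, recovering 87% of the planted two-fold
effects at this noise level. The other scripts in `examples/` demonstrate
the proteome gap filter with derived cutoffs
(`02_proteome_gap_filter.py` prints a derived fold-change cutoff of 0.315,
typical of three-replicate TMT noise), enrichment plus the Dice term
network, and the cross-omics integration arithmetic.

The same stages are scriptable from the shell via the thin `permomics` CLI
(`simulate`, `normalize`, `diffexp`, `diffprot`, `cohort`, `enrich`,
`netbuild`, `integrate`, `all`); `permomics all --seed 1 --out-dir run/`
executes the whole pipeline on synthetic inputs and writes a manifest with
every derived cutoff and checksums of all outputs.

## Layout

- `src/permomics/` — `synthio` (generators), `normalize`, `diffexpr`,
  `enrich`, `gobpnet`, `integrate`, `io`, `pipeline`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `tests/` — unit, property and acceptance suites.
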