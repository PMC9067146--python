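"""Synthetic multi-omics data with planted effects and ground truth.

Generators emulate the study design the downstream statistics assume: three
cell types, two conditions (control vs treated), three replicates each, with
a fraction of features planted up- or down-regulated at a chosen log2
fold-change and log-normal replicate noise.  A cohort generator produces a
single large two-group comparison (e.g. 115 vs 535 tumour samples, scaled
down by default).  Every generator is a pure function of its design and
seed: one global seed fans out to independent substreams per generator so
adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSet, GeneSetCollection, InvalidDesignError, OmicsMatrix

MODULE_NAMES = ("metabolism", "cell_proliferation", "cell_development", "immune_response")

# substream tags keep the generators' random streams independent of each other
_STREAM = {"expression": 11, "proteome": 23, "annotation": 37, "cohort": 53}


def _rng(seed: int, stream: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM[stream], salt]))


@dataclass
class SimDesign:
    """Design of a planted-effect two-condition experiment.

    All log-scale quantities are on the log2 scale.  ``frac_expressed``
    controls the fraction of features whose baseline is kept above the
    downstream expressed filter (FPKM >= 1); the remainder are forced below
    it in every sample.
    """

    n_features: int = 1000
    n_cell_types: int = 3
    replicates_per_group: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    frac_expressed: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_cell_types < 1 or self.replicates_per_group < 1:
            raise InvalidDesignError("all counts must be >= 1")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise InvalidDesignError("frac_up/frac_down must be proportions")
        if self.frac_up + self.frac_down > 1:
            raise InvalidDesignError("frac_up + frac_down must be <= 1")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        if self.effect_log2fc < 0:
            raise InvalidDesignError("effect_log2fc must be >= 0")
        if not (0 <= self.frac_expressed <= 1):
            raise InvalidDesignError("frac_expressed must be a proportion")
        if self.baseline_log_sd < 0:
            raise InvalidDesignError("baseline_log_sd must be >= 0")


def protein_design(**overrides) -> SimDesign:
    """Default proteome design: tighter replicate noise and smaller effects,
    sized so a permutation-null-derived fold-change cutoff lands in the
    0.26-0.33 range typical of three-replicate TMT comparisons."""
    base = dict(
        n_features=1000,
        frac_up=0.05,
        frac_down=0.05,
        effect_log2fc=0.5,
        noise_sd=0.18,
        baseline_log_mean=0.0,
        baseline_log_sd=1.0,
        frac_expressed=1.0,
    )
    base.update(overrides)
    return SimDesign(**base)


def _feature_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _plant_directions(
    rng: np.random.Generator, n_features: int, frac_up: float, frac_down: float
) -> np.ndarray:
    """Return per-feature planted direction codes: +1 up, -1 down, 0 null."""
    n_up = int(round(frac_up * n_features))
    n_down = int(round(frac_down * n_features))
    order = rng.permutation(n_features)
    codes = np.zeros(n_features, dtype=int)
    codes[order[:n_up]] = 1
    codes[order[n_up : n_up + n_down]] = -1
    return codes


def _truth_frame(cell_type: str, feature_ids, codes: np.ndarray, effect: float) -> pd.DataFrame:
    direction = np.where(codes > 0, "up", np.where(codes < 0, "down", "null"))
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "cell_type": cell_type,
            "direction": direction,
            "planted_log2fc": codes * effect,
        }
    )


def generate_expression(design: SimDesign) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Simulate an FPKM-scale transcript matrix with planted effects.

    Returns the matrix (``n_features`` x ``n_cell_types * 2 * replicates``)
    and a truth table with one row per (feature, cell type) recording the
    planted direction and log2 fold-change.  Control values come from a
    log-normal baseline (normal on the log2 scale); treated values are the
    control baseline shifted by the planted log2FC; replicate noise is
    normal on the log2 scale.  A ``1 - frac_expressed`` fraction of features
    is forced below FPKM 1 in all samples so the expressed filter has work
    to do.
    """
    ids = _feature_ids(design.n_features)
    rng0 = _rng(design.seed, "expression")
    baseline = rng0.normal(design.baseline_log_mean, design.baseline_log_sd, design.n_features)
    n_unexpressed = int(round((1 - design.frac_expressed) * design.n_features))
    unexpressed = rng0.choice(design.n_features, size=n_unexpressed, replace=False)
    # force well below the FPKM=1 filter regardless of noise draw
    baseline[unexpressed] = rng0.uniform(-6.0, -2.0, n_unexpressed)

    cols, data, meta_rows, truths = [], [], [], []
    for ct in range(design.n_cell_types):
        cell = f"CT{ct + 1}"
        rng = _rng(design.seed, "expression", salt=ct + 1)
        codes = _plant_directions(rng, design.n_features, design.frac_up, design.frac_down)
        truths.append(_truth_frame(cell, ids, codes, design.effect_log2fc))
        for condition, shift in (("control", 0.0), ("treated", 1.0)):
            for rep in range(1, design.replicates_per_group + 1):
                log2vals = (
                    baseline
                    + shift * codes * design.effect_log2fc
                    + rng.normal(0.0, design.noise_sd, design.n_features)
                )
                data.append(np.exp2(log2vals))
                sid = f"{cell}_{condition}_r{rep}"
                cols.append(sid)
                meta_rows.append({"sample_id": sid, "cell_type": cell,
                                  "condition": condition, "replicate": rep})

    values = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.concat(truths, ignore_index=True)
    return OmicsMatrix(values, metadata, "fpkm"), truth


def generate_proteome(
    design: SimDesign,
    coupling: float = 0.5,
    expression_truth: pd.DataFrame | None = None,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Simulate a log-abundance protein matrix partially coupled to a
    transcript truth table.

    A ``coupling`` fraction of the planted protein effects is copied
    (feature, cell type and direction) from ``expression_truth``; the rest
    is planted independently, emulating partial mRNA/protein concordance.
    Values are continuous log2 abundances (the ``protein`` layer), used
    directly by the differential stage without further transformation.
    """
    if not (0.0 <= coupling <= 1.0):
        raise InvalidDesignError("coupling must be in [0, 1]")
    ids = _feature_ids(design.n_features)
    rng0 = _rng(design.seed, "proteome")
    baseline = rng0.normal(design.baseline_log_mean, design.baseline_log_sd, design.n_features)

    cols, data, meta_rows, truths = [], [], [], []
    for ct in range(design.n_cell_types):
        cell = f"CT{ct + 1}"
        rng = _rng(design.seed, "proteome", salt=ct + 1)
        codes = _planted_codes_coupled(rng, design, cell, ids, coupling, expression_truth)
        truths.append(_truth_frame(cell, ids, codes, design.effect_log2fc))
        for condition, shift in (("control", 0.0), ("treated", 1.0)):
            for rep in range(1, design.replicates_per_group + 1):
                log2vals = (
                    baseline
                    + shift * codes * design.effect_log2fc
                    + rng.normal(0.0, design.noise_sd, design.n_features)
                )
                data.append(log2vals)
                sid = f"{cell}_{condition}_r{rep}"
                cols.append(sid)
                meta_rows.append({"sample_id": sid, "cell_type": cell,
                                  "condition": condition, "replicate": rep})

    values = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.concat(truths, ignore_index=True)
    return OmicsMatrix(values, metadata, "protein"), truth


def _planted_codes_coupled(rng, design, cell, ids, coupling, expression_truth):
    n = design.n_features
    n_up = int(round(design.frac_up * n))
    n_down = int(round(design.frac_down * n))
    codes = np.zeros(n, dtype=int)
    if expression_truth is None:
        return _plant_directions(rng, n, design.frac_up, design.frac_down)

    idx = {fid: i for i, fid in enumerate(ids)}
    sub = expression_truth[expression_truth["cell_type"] == cell]
    expr_up = [idx[f] for f in sub.loc[sub["direction"] == "up", "feature_id"] if f in idx]
    expr_down = [idx[f] for f in sub.loc[sub["direction"] == "down", "feature_id"] if f in idx]

    for code, want, pool in ((1, n_up, expr_up), (-1, n_down, expr_down)):
        n_shared = min(int(round(coupling * want)), len(pool))
        shared = rng.choice(pool, size=n_shared, replace=False) if n_shared else np.array([], int)
        codes[shared] = code
        # remainder planted uniformly among unassigned features, so at
        # coupling=0 any overlap with the transcript truth is chance-level
        free = np.flatnonzero(codes == 0)
        extra = want - n_shared
        if extra > 0:
            picked = rng.choice(free, size=extra, replace=False)
            codes[picked] = code
    return codes


def generate_annotation(
    n_terms: int = 50,
    size_range: tuple[int, int] = (10, 40),
    n_genes: int = 1000,
    n_modules: int = 4,
    seed: int = 0,
    focus_sets: list | None = None,
    focus_frac: float = 0.5,
) -> GeneSetCollection:
    """Generate a gene-set collection with guaranteed within-module overlap.

    Terms cycle over ``n_modules`` module labels; consecutive terms within a
    module share at least three members, so every term has a same-module
    partner reachable by the shared>=3 edge rule.  Term levels cycle over
    2-4, mimicking mid-level ontology terms grouped under level-1 modules.

    ``focus_sets`` optionally plants enrichment signal: alternate terms draw
    a ``focus_frac`` fraction of their members from one of the given feature
    sets (cycling), so a differential list drawn from a focus set is
    genuinely enriched in those terms.
    """
    lo, hi = size_range
    if lo < 3:
        raise InvalidDesignError("minimum term size must be >= 3")
    if hi > n_genes:
        raise InvalidDesignError("size_range exceeds the gene universe")
    if n_modules < 1:
        raise InvalidDesignError("n_modules must be >= 1")
    if n_terms < 2 * n_modules:
        raise InvalidDesignError("need at least two terms per module for guaranteed overlap")
    rng = _rng(seed, "annotation")
    universe = np.array(_feature_ids(n_genes))
    module_names = [
        MODULE_NAMES[m] if m < len(MODULE_NAMES) else f"module_{m + 1}" for m in range(n_modules)
    ]

    coll = GeneSetCollection()
    prev_in_module: dict[str, frozenset] = {}
    for t in range(n_terms):
        module = module_names[t % n_modules]
        size = int(rng.integers(lo, hi + 1))
        anchor = prev_in_module.get(module)
        members: list = []
        if anchor is not None:
            members += list(rng.choice(sorted(anchor), size=3, replace=False))
        if focus_sets and t % 2 == 0:
            focus = set(focus_sets[(t // 2) % len(focus_sets)]) & set(universe)
            pool = np.array(sorted(focus - set(members)))
            n_focus = min(int(round(focus_frac * (size - len(members)))), len(pool))
            if n_focus > 0:
                members += list(rng.choice(pool, size=n_focus, replace=False))
        rest_pool = np.array(sorted(set(universe) - set(members)))
        members += list(rng.choice(rest_pool, size=size - len(members), replace=False))
        term = GeneSet(
            term_id=f"T{t:04d}",
            name=f"synthetic process {t}",
            level=2 + (t % 3),
            module=module,
            members=frozenset(members),
        )
        coll.add(term)
        prev_in_module[module] = term.members
    return coll


def generate_cohort(
    n_group_a: int = 20,
    n_group_b: int = 80,
    n_features: int = 1000,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    effect_log2fc: float = 0.5,
    noise_sd: float = 0.5,
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 1.5,
    frac_expressed: float = 0.8,
    seed: int = 0,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Simulate a two-group cohort comparison (e.g. tumour subtype A vs B).

    Mirrors a large unbalanced clinical design (defaults scaled down from a
    115-vs-535 comparison); group A carries the planted subtype effects.
    """
    if n_group_a < 2 or n_group_b < 2:
        raise InvalidDesignError("both cohort group sizes must be >= 2")
    design = SimDesign(
        n_features=n_features,
        n_cell_types=1,
        replicates_per_group=2,  # unused; validated via explicit sizes below
        frac_up=frac_up,
        frac_down=frac_down,
        effect_log2fc=effect_log2fc,
        noise_sd=noise_sd,
        baseline_log_mean=baseline_log_mean,
        baseline_log_sd=baseline_log_sd,
        frac_expressed=frac_expressed,
        seed=seed,
    )
    ids = _feature_ids(n_features)
    rng = _rng(seed, "cohort")
    baseline = rng.normal(baseline_log_mean, baseline_log_sd, n_features)
    n_unexpressed = int(round((1 - frac_expressed) * n_features))
    unexpressed = rng.choice(n_features, size=n_unexpressed, replace=False)
    baseline[unexpressed] = rng.uniform(-6.0, -2.0, n_unexpressed)
    codes = _plant_directions(rng, n_features, frac_up, frac_down)

    cols, data, meta_rows = [], [], []
    for group, n_samp, shift in (("group_a", n_group_a, 1.0), ("group_b", n_group_b, 0.0)):
        for i in range(1, n_samp + 1):
            log2vals = (
                baseline + shift * codes * effect_log2fc + rng.normal(0.0, noise_sd, n_features)
            )
            data.append(np.exp2(log2vals))
            sid = f"{group}_s{i:03d}"
            cols.append(sid)
            meta_rows.append({"sample_id": sid, "group": group})

    values = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = _truth_frame("cohort", ids, codes, design.effect_log2fc)
    return OmicsMatrix(values, metadata, "fpkm"), truth
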