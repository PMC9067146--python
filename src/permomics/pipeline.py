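"""End-to-end orchestration: simulate -> normalize -> differential ->
enrichment -> term network -> integration, with a run manifest.

The pipeline is deterministic under a fixed configuration: the same config
and seed reproduce byte-identical result tables.  Every derived quantity
(null-percentile fold-change cutoffs, gap cutoffs, Dice cutoffs) is logged
when computed and recorded in the manifest with its derivation mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .containers import OmicsMatrix, PermomicsError
from .diffexpr import ComparisonSpec, run_comparison
from .enrich import categorize_level1, enrich_lists
from .gobpnet import build_term_graph, cluster_and_group, term_member_sets
from .integrate import CallSets, map_to_pathway, venn_counts
from .normalize import filter_expressed, log_transform, quantile_normalize
from .synthio import SimDesign, generate_annotation, generate_expression, generate_proteome, protein_design

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; loadable from YAML."""

    out_dir: str = "permomics_run"
    seed: int = 0
    # simulation
    n_features: int = 1000
    n_cell_types: int = 3
    replicates_per_group: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25
    frac_expressed: float = 0.8
    proteome_coupling: float = 0.5
    # annotation
    n_terms: int = 60
    term_size_range: tuple = (10, 40)
    n_modules: int = 4
    # differential testing
    n_permutations: int = 1000
    p_cutoff_deg: float = 0.05
    fc_cutoff_deg: float = 0.58
    p_cutoff_dep: float = 0.2
    gap_signed: bool = False
    # networks
    min_shared: int = 3
    dice_percentile: float = 95.0
    dice_universe: str = "list"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PermomicsError(f"unknown config keys: {sorted(unknown)}")
        if "term_size_range" in raw:
            raw["term_size_range"] = tuple(raw["term_size_range"])
        return cls(**raw)


def _comparison(matrix: OmicsMatrix, cell_type: str, seed: int, n_perm: int) -> ComparisonSpec:
    a = matrix.samples_where(cell_type=cell_type, condition="treated")
    b = matrix.samples_where(cell_type=cell_type, condition="control")
    return ComparisonSpec(group_a=a, group_b=b, n_permutations=n_perm, seed=seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic inputs; returns the manifest dict.

    Writes, under ``config.out_dir``: the simulated matrices and truth
    tables, the normalized transcript matrix, per-cell-type differential
    result tables for both omics layers, enrichment tables, up/down term
    networks (GraphML + edge TSV), Venn/overlap summaries, and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "cutoffs": {}, "counts": {}}

    # --- simulate ------------------------------------------------------
    design = SimDesign(
        n_features=config.n_features,
        n_cell_types=config.n_cell_types,
        replicates_per_group=config.replicates_per_group,
        frac_up=config.frac_up,
        frac_down=config.frac_down,
        effect_log2fc=config.effect_log2fc,
        noise_sd=config.noise_sd,
        frac_expressed=config.frac_expressed,
        seed=config.seed,
    )
    expr, expr_truth = generate_expression(design)
    prot_design = protein_design(
        n_features=config.n_features,
        n_cell_types=config.n_cell_types,
        replicates_per_group=config.replicates_per_group,
        frac_up=config.frac_up,
        frac_down=config.frac_down,
        seed=config.seed,
    )
    prot, prot_truth = generate_proteome(prot_design, config.proteome_coupling, expr_truth)
    planted_up = set(expr_truth.loc[expr_truth["direction"] == "up", "feature_id"])
    planted_down = set(expr_truth.loc[expr_truth["direction"] == "down", "feature_id"])
    annotation = generate_annotation(
        n_terms=config.n_terms,
        size_range=tuple(config.term_size_range),
        n_genes=config.n_features,
        n_modules=config.n_modules,
        seed=config.seed,
        focus_sets=[planted_up, planted_down],
    )
    pio.write_matrix(expr, out / "expression_fpkm.tsv", out / "expression_samples.tsv")
    pio.write_matrix(prot, out / "proteome.tsv", out / "proteome_samples.tsv")
    pio.write_truth(expr_truth, out / "expression_truth.tsv")
    pio.write_truth(prot_truth, out / "proteome_truth.tsv")
    pio.write_gmt(annotation, out / "annotation.gmt")

    # --- normalize + differential per cell type ------------------------
    cell_types = sorted(expr.metadata["cell_type"].unique())
    deg_results, dep_results = {}, {}
    backgrounds = {}
    for ct in cell_types:
        sub = expr.subset_samples(expr.samples_where(cell_type=ct))
        filtered = filter_expressed(sub, mode="all_min", threshold=1.0)
        norm = quantile_normalize(log_transform(filtered))
        backgrounds[ct] = set(norm.feature_ids)
        spec = _comparison(norm, ct, config.seed, config.n_permutations)
        stats, cutoffs, _ = run_comparison(norm, spec, preset="deg")
        deg_results[ct] = stats
        manifest["cutoffs"][f"deg_{ct}"] = {
            "p": cutoffs.p_cutoff, "fc": cutoffs.fc_cutoff, "mode": cutoffs.fc_mode}
        log.info("DEG %s: fc cutoff %.3f (fixed), %d up / %d down", ct,
                 cutoffs.fc_cutoff, (stats["call"] == "up").sum(), (stats["call"] == "down").sum())
        pio.write_stats(stats, out / f"deg_{ct}.tsv")

        psub = prot.subset_samples(prot.samples_where(cell_type=ct))
        pspec = _comparison(psub, ct, config.seed, config.n_permutations)
        pstats, pcut, _ = run_comparison(psub, pspec, preset="dep", gap_signed=config.gap_signed)
        dep_results[ct] = pstats
        manifest["cutoffs"][f"dep_{ct}"] = {
            "p": pcut.p_cutoff, "fc": pcut.fc_cutoff, "fc_mode": pcut.fc_mode,
            "gap": pcut.gap_cutoff, "gap_mode": pcut.gap_mode}
        log.info("DEP %s: derived fc cutoff %.3f, gap cutoff %s", ct, pcut.fc_cutoff,
                 f"{pcut.gap_cutoff:.4f}" if pcut.gap_cutoff is not None else "n/a")
        pio.write_stats(pstats, out / f"dep_{ct}.tsv")

    deg_calls = CallSets.from_results(deg_results)
    dep_calls = CallSets.from_results(dep_results)

    # --- integration: Venn + cross-omics overlap -----------------------
    overlap_rows = []
    for direction in ("up", "down"):
        v = venn_counts(deg_calls.direction_sets(direction))
        manifest["counts"][f"deg_{direction}_union"] = v["union"]
        manifest["counts"][f"deg_{direction}_triple"] = v["triple"]
        vp = venn_counts(dep_calls.direction_sets(direction))
        manifest["counts"][f"dep_{direction}_union"] = vp["union"]
        manifest["counts"][f"dep_{direction}_triple"] = vp["triple"]
        genes = deg_calls.union(direction)
        prots = dep_calls.union(direction)
        shared = len(genes & prots)
        overlap_rows.append({
            "direction": direction,
            "n_genes": len(genes),
            "n_proteins": len(prots),
            "shared": shared,
        })
    pd.DataFrame(overlap_rows).to_csv(out / "cross_omics_overlap.tsv", sep="\t", index=False)

    # --- enrichment + term networks ------------------------------------
    background = set().union(*backgrounds.values()) if backgrounds else set()
    enr = enrich_lists(deg_calls.union("up"), deg_calls.union("down"), annotation, background)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format=pio.FLOAT_FMT)
    shares = categorize_level1(enr, annotation)
    shares.to_csv(out / "module_shares.tsv", sep="\t", index=False, float_format=pio.FLOAT_FMT)

    for direction in ("up", "down"):
        rows = enr[(enr["direction"] == direction) & enr["significant"]]
        feat_list = deg_calls.union(direction)
        members = term_member_sets(rows, annotation, feat_list, universe=config.dice_universe)
        graph = build_term_graph(
            rows, members, min_shared=config.min_shared, dice_percentile=config.dice_percentile
        )
        graph = cluster_and_group(graph)
        manifest["cutoffs"][f"dice_{direction}"] = graph.graph.get("dice_cutoff")
        manifest["counts"][f"termnet_{direction}_nodes"] = graph.number_of_nodes()
        manifest["counts"][f"termnet_{direction}_edges"] = graph.number_of_edges()
        log.info("term network (%s): %d nodes, %d edges, dice cutoff %.3f", direction,
                 graph.number_of_nodes(), graph.number_of_edges(),
                 graph.graph.get("dice_cutoff", float("nan")))
        pio.write_graphml(graph, out / f"termnet_{direction}.graphml")
        edge_rows = [
            {"term_i": u, "term_j": v, "shared": d["shared"], "dice": d["dice"]}
            for u, v, d in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(edge_rows, columns=["term_i", "term_j", "shared", "dice"]).to_csv(
            out / f"termnet_{direction}_edges.tsv", sep="\t", index=False,
            float_format=pio.FLOAT_FMT)

    # --- attribute mapping onto a small planted pathway ----------------
    de_union = sorted(deg_calls.union("up") | deg_calls.union("down"))
    pathway_nodes = de_union[:10]
    if len(pathway_nodes) >= 2:
        node_kinds = {n: "gene" for n in pathway_nodes}
        edges = pd.DataFrame(
            {
                "source": pathway_nodes[:-1],
                "interaction": ["reaction"] * (len(pathway_nodes) - 1),
                "target": pathway_nodes[1:],
            }
        )
        pio.write_sif(edges, out / "pathway.sif")
        pio.write_node_kinds(node_kinds, out / "pathway_nodes.tsv")
        pgraph = map_to_pathway(edges, node_kinds, deg_calls)
        pio.write_graphml(pgraph, out / "pathway_annotated.graphml")
        manifest["counts"]["pathway_nodes"] = pgraph.number_of_nodes()

    # --- manifest ------------------------------------------------------
    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.suffix in (".tsv", ".gmt", ".sif", ".graphml")
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
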