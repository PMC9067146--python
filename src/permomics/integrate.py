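"""Cross-omics set algebra and molecular-network attribute mapping.

Covers the integration arithmetic of a three-cell-type two-omics study:
Venn region counts across cell types, overlap percentages between gene- and
protein-level calls, and the decoration of a supplied interaction network
(SIF-style edge list) with per-node colour (the log2 fold-change of maximal
magnitude across cell types) and label-size class (in how many cell types
the node was called differential).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .containers import PermomicsError

log = logging.getLogger(__name__)

LABEL_CLASSES = {3: "large", 2: "middle", 1: "small", 0: "non_de"}


@dataclass
class CallSets:
    """Differential calls per cell type and direction, plus per-feature log2FCs.

    ``calls``: {cell_type: {"up": set, "down": set}};
    ``log2fc``: {cell_type: {feature_id: log2fc}}.
    """

    calls: dict = field(default_factory=dict)
    log2fc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ct, d in self.calls.items():
            if set(d.get("up", ())) & set(d.get("down", ())):
                raise PermomicsError(f"up/down sets overlap in {ct}")

    @classmethod
    def from_results(cls, results: dict) -> "CallSets":
        """Build from {cell_type: stats DataFrame with call/log2fc columns}."""
        calls, fcs = {}, {}
        for ct, df in results.items():
            calls[ct] = {
                "up": set(df.index[df["call"] == "up"]),
                "down": set(df.index[df["call"] == "down"]),
            }
            fcs[ct] = df["log2fc"].to_dict()
        return cls(calls, fcs)

    def direction_sets(self, direction: str) -> dict:
        return {ct: set(d.get(direction, ())) for ct, d in self.calls.items()}

    def union(self, direction: str) -> set:
        out = set()
        for s in self.direction_sets(direction).values():
            out |= s
        return out

    def n_cell_types_called(self, feature: str) -> int:
        return sum(
            feature in d.get("up", ()) or feature in d.get("down", ())
            for d in self.calls.values()
        )


def venn_counts(sets: dict) -> dict:
    """Disjoint region counts of a 3-set Venn diagram.

    Keys are frozensets of set names naming the region (features in exactly
    those sets); also returns ``union`` and ``triple`` totals.
    """
    if len(sets) < 2:
        raise PermomicsError("venn_counts needs at least 2 sets")
    names = sorted(sets)
    universe = set().union(*sets.values())
    regions = {}
    for feature in universe:
        membership = frozenset(n for n in names if feature in sets[n])
        regions[membership] = regions.get(membership, 0) + 1
    out = {"regions": regions, "union": len(universe)}
    out["triple"] = regions.get(frozenset(names), 0) if len(names) == 3 else None
    return out


def overlap_fraction(
    shared: int, total: int, as_percent: bool = True, decimals: int = 1
) -> float:
    """Overlap share = shared/total, optionally as a percentage, rounded
    half-away-from-zero to ``decimals`` places (so 216/535 prints 40.4%)."""
    if total <= 0:
        raise PermomicsError("total must be > 0")
    if not (0 <= shared <= total):
        raise PermomicsError("need 0 <= shared <= total")
    x = shared / total
    if as_percent:
        x *= 100.0
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


def map_to_pathway(
    edges: pd.DataFrame,
    node_kinds: dict,
    call_sets: CallSets,
    colour_rule: str = "absmax",
) -> nx.DiGraph:
    """Decorate an interaction network with differential-call attributes.

    ``edges`` is a SIF-style table with columns source, interaction, target;
    ``node_kinds`` maps node id -> kind in {gene, metabolite, complex}.
    Gene nodes get a ``colour`` (log2FC across cell types: the value of
    maximal magnitude with sign retained under ``absmax``, or the plain
    signed maximum under ``signed_max``) and a ``label_class`` in
    {large, middle, small, non_de} counting in how many cell types the gene
    was called differential.  Edges naming unknown nodes are skipped with a
    warning; the count is stored in ``graph["skipped_edges"]``.
    """
    if colour_rule not in ("absmax", "signed_max"):
        raise PermomicsError(f"unknown colour rule {colour_rule!r}")
    g = nx.DiGraph()
    for node, kind in node_kinds.items():
        if kind not in ("gene", "metabolite", "complex"):
            raise PermomicsError(f"unknown node kind {kind!r} for {node}")
        g.add_node(node, kind=kind)
        if kind != "gene":
            continue
        fcs = [d[node] for d in call_sets.log2fc.values() if node in d]
        if fcs:
            if colour_rule == "absmax":
                colour = max(fcs, key=abs)
            else:
                colour = max(fcs)
        else:
            colour = 0.0
        n_called = call_sets.n_cell_types_called(node)
        g.nodes[node]["colour"] = float(colour)
        g.nodes[node]["n_de_cell_types"] = n_called
        g.nodes[node]["label_class"] = LABEL_CLASSES.get(min(n_called, 3), "non_de")
    skipped = 0
    for _, r in edges.iterrows():
        src, kind, tgt = r["source"], r["interaction"], r["target"]
        if src not in g or tgt not in g:
            skipped += 1
            log.warning("skipping edge %s-%s-%s: unknown node", src, kind, tgt)
            continue
        g.add_edge(src, tgt, interaction=kind)
    g.graph["skipped_edges"] = skipped
    return g
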