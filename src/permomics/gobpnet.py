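"""Term-association (enrichment-map) network construction.

Enriched terms become nodes; two terms are connected when they share at
least ``min_shared`` members (default 3) and their Sørensen–Dice
coefficient, 2|Pi∩Pj|/(|Pi|+|Pj|), strictly exceeds a cutoff.  The cutoff
is either fixed or derived per direction as the 95th percentile of the
Dice values over all candidate pairs (those passing the shared-members
rule).  Communities come from seeded greedy modularity maximization and
each community is labelled with the majority level-1 module of its terms.

Member sets default to the analyzed list's members of each term (the genes
or proteins from the differential list annotated to the term), switchable
to full term membership via ``universe="term"``.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GeneSetCollection, PermomicsError


def dice(set_a, set_b) -> float:
    """Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|); symmetric, in [0, 1]."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise PermomicsError("dice requires non-empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def term_member_sets(
    rows: pd.DataFrame,
    collection: GeneSetCollection,
    feature_list: set,
    universe: str = "list",
) -> dict:
    """Member set per enriched term: list-restricted (default) or full term."""
    if universe not in ("list", "term"):
        raise PermomicsError(f"unknown dice universe {universe!r}")
    feature_list = set(feature_list)
    out = {}
    for tid in rows["term_id"]:
        members = set(collection[tid].members)
        if universe == "list":
            members &= feature_list
        if members:
            out[tid] = members
    return out


def candidate_pairs(member_sets: dict, min_shared: int = 3) -> pd.DataFrame:
    """All unordered term pairs sharing >= ``min_shared`` members, with
    shared counts and Dice coefficients."""
    if len(member_sets) < 2:
        return pd.DataFrame(columns=["term_i", "term_j", "shared", "dice"])
    terms = sorted(member_sets)
    rows = []
    for i, ti in enumerate(terms):
        for tj in terms[i + 1 :]:
            shared = len(member_sets[ti] & member_sets[tj])
            if shared >= min_shared:
                rows.append(
                    {
                        "term_i": ti,
                        "term_j": tj,
                        "shared": shared,
                        "dice": dice(member_sets[ti], member_sets[tj]),
                    }
                )
    return pd.DataFrame(rows, columns=["term_i", "term_j", "shared", "dice"])


def derive_dice_cutoff(dice_values, percentile: float = 95.0) -> float:
    """Similarity cutoff = linear-interpolation percentile (default 95th) of
    the candidate-pair Dice distribution.  Computed per direction, since the
    up- and down-networks have distinct similarity distributions."""
    vals = np.asarray(dice_values, dtype=float)
    if vals.size == 0:
        raise PermomicsError("no candidate dice values to derive a cutoff from")
    return float(np.percentile(vals, percentile, method="linear"))


def build_term_graph(
    rows: pd.DataFrame,
    member_sets: dict,
    min_shared: int = 3,
    dice_cutoff: float | None = None,
    dice_percentile: float = 95.0,
) -> nx.Graph:
    """Build the association network for one direction's enriched terms.

    Edges are exactly the candidate pairs (shared >= min_shared) whose Dice
    coefficient strictly exceeds the cutoff; isolated enriched terms are
    retained as nodes.  When ``dice_cutoff`` is None it is derived from the
    candidate distribution at ``dice_percentile``.
    """
    g = nx.Graph()
    for _, r in rows.iterrows():
        tid = r["term_id"]
        if tid not in member_sets:
            continue
        g.add_node(
            tid,
            name=r.get("name", tid),
            direction=r["direction"],
            p_ease=float(r["p_ease"]),
            module=r["module"],
            set_size=len(member_sets[tid]),
        )
    pairs = candidate_pairs({t: member_sets[t] for t in g.nodes}, min_shared=min_shared)
    if dice_cutoff is None:
        if len(pairs):
            dice_cutoff = derive_dice_cutoff(pairs["dice"], dice_percentile)
        else:
            dice_cutoff = 1.0
    g.graph["dice_cutoff"] = float(dice_cutoff)
    g.graph["min_shared"] = int(min_shared)
    for _, r in pairs.iterrows():
        if r["dice"] > dice_cutoff:
            g.add_edge(r["term_i"], r["term_j"], shared=int(r["shared"]), dice=float(r["dice"]))
    return g


def cluster_and_group(graph: nx.Graph) -> nx.Graph:
    """Assign community ids by greedy modularity maximization and label each
    community with the majority level-1 module of its member terms (ties
    broken lexicographically).  Deterministic for a fixed graph."""
    g = graph.copy()
    if g.number_of_nodes() == 0:
        return g
    if g.number_of_edges() == 0:
        communities = [{n} for n in sorted(g.nodes)]
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
        communities.sort(key=lambda c: sorted(c)[0])
    for cid, members in enumerate(communities):
        labels = sorted(g.nodes[n].get("module", "") for n in members)
        counts = pd.Series(labels).value_counts()
        top = counts.max()
        majority = sorted(m for m in counts.index if counts[m] == top)[0]
        for n in members:
            g.nodes[n]["community"] = cid
            g.nodes[n]["community_module"] = majority
    return g
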