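"""EASE enrichment and the Dice term-association network.

Builds an annotation in which half the terms oversample a planted gene set,
enriches that gene list, then links significant terms that share >= 3 genes
with a Sørensen-Dice coefficient above the 95th percentile of the
candidate-pair distribution, and clusters the network into modules.
"""

import permomics as pm

planted = {f"g{i:05d}" for i in range(80)}
background = {f"g{i:05d}" for i in range(800)}

collection = pm.generate_annotation(
    n_terms=40, size_range=(15, 30), n_genes=800, n_modules=4, seed=5,
    focus_sets=[planted])

rows = pm.enrich_lists(planted, set(), collection, background)
sig = rows[rows["significant"]]
print(f"{len(sig)} of {len(collection)} terms enriched at EASE p < 0.05")
print(sig[["term_id", "module", "overlap", "term_size", "p_ease"]]
      .head(5).to_string(index=False))

members = pm.term_member_sets(sig, collection, planted, universe="list")
graph = pm.build_term_graph(sig, members, min_shared=3, dice_percentile=95.0)
graph = pm.cluster_and_group(graph)

print(f"\nnetwork: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges, "
      f"derived dice cutoff {graph.graph['dice_cutoff']:.3f}")
shares = pm.categorize_level1(rows, collection)
print("\nlevel-1 module shares of enriched terms:")
print(shares.to_string(index=False))
# Edges mark term pairs whose annotated gene lists overlap far more than
# typical for this enrichment result; communities group them into the
# level-1 processes (metabolism, proliferation, development, immune).
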