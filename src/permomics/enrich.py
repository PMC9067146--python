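"""EASE-score gene-set enrichment and level-1 module categorization.

The EASE score is a conservative variant of the one-tailed
Fisher/hypergeometric enrichment p-value: one overlapping gene is removed
before the upper tail is taken, so a single-gene overlap can never be
significant.  For list size n, term size K, background N and overlap k, the
score is P(X >= k-1) with X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection, PermomicsError

P_SIGNIFICANT = 0.05


def ease_pvalue(N: int, K: int, n: int, k: int) -> float:
    """EASE enrichment p: hypergeometric upper tail with one success removed.

    ``k = 0`` returns 1 by convention; ``k = 1`` also returns 1 (removing
    the only success leaves the full tail).
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise PermomicsError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    # sf(k-2) = P(X > k-2) = P(X >= k-1)
    return float(min(1.0, hypergeom.sf(k - 2, N, K, n)))


def enrich_lists(
    up: set,
    down: set,
    collection: GeneSetCollection,
    background: set,
) -> pd.DataFrame:
    """EASE enrichment of the up and down feature lists against a collection.

    Term member sets are intersected with the background before testing;
    rows with zero overlap are dropped; the ``significant`` flag marks
    p < 0.05 (strict).  Rows are sorted by p then term id.
    """
    background = set(background)
    if not background:
        raise PermomicsError("empty background universe")
    restricted = collection.restricted_to(background)
    rows = []
    for direction, feat_list in (("up", set(up) & background), ("down", set(down) & background)):
        n = len(feat_list)
        if n == 0:
            continue
        for term in restricted:
            k = len(term.members & feat_list)
            if k == 0:
                continue
            K = len(term.members)
            p = ease_pvalue(len(background), K, n, k)
            rows.append(
                {
                    "term_id": term.term_id,
                    "name": term.name,
                    "level": term.level,
                    "module": term.module,
                    "direction": direction,
                    "n_list": n,
                    "term_size": K,
                    "background_size": len(background),
                    "overlap": k,
                    "p_ease": p,
                    "significant": p < P_SIGNIFICANT,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "name", "level", "module", "direction", "n_list",
                     "term_size", "background_size", "overlap", "p_ease", "significant"]
        )
    out = pd.DataFrame(rows).sort_values(["direction", "p_ease", "term_id"])
    return out.reset_index(drop=True)


def categorize_level1(rows: pd.DataFrame, collection: GeneSetCollection) -> pd.DataFrame:
    """Per-direction percentage of enriched terms falling in each level-1 module.

    Takes the significant rows of an enrichment table and returns the
    pie-chart-style module shares; percentages within a direction sum to
    100 up to rounding.
    """
    sig = rows[rows["significant"]].copy()
    for tid in sig["term_id"]:
        if tid not in collection:
            raise PermomicsError(f"enriched term {tid} missing from collection")
        if not collection[tid].module:
            raise PermomicsError(f"term {tid} has no module label")
    shares = []
    for direction, sub in sig.groupby("direction"):
        counts = sub.groupby("module")["term_id"].count()
        total = counts.sum()
        for module, cnt in counts.sort_index().items():
            shares.append(
                {
                    "direction": direction,
                    "module": module,
                    "n_terms": int(cnt),
                    "percent": 100.0 * cnt / total,
                }
            )
    return pd.DataFrame(shares, columns=["direction", "module", "n_terms", "percent"])
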