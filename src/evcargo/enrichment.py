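"""Overrepresentation analysis with Bonferroni control.

One-sided hypergeometric tail per annotation term: with N background ids,
K term members in the background, and a query of n ids overlapping the
term in k, p = P[X >= k] for X ~ Hypergeom(N, K, n). The Bonferroni
multiplier is the number of terms actually tested (non-empty intersection
with the background), not the catalogue size.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from evcargo.datatypes import AnnotationSets

ENRICH_COLUMNS = [
    "term_id", "term_name", "k", "K", "n", "N",
    "query_fraction", "p_value", "p_bonferroni",
]


def overrepresentation(
    query: set[str],
    sets: AnnotationSets,
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric ORA of ``query`` against each term, within ``background``.

    The query must be a subset of the background; term member sets are
    intersected with the background before testing. Terms with zero overlap
    are reported with p = 1. Results are sorted by p (ties by term id).
    ``query_fraction`` is k/n, the share of the query carrying the term.
    """
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= set(background):
        extra = sorted(query - set(background))[:5]
        raise ValueError(f"query ids outside background: {extra}")
    n = len(query)
    N = len(background)
    rows = []
    for tid, (name, members) in sets.terms.items():
        members_bg = members & set(background)
        if not members_bg:
            continue
        K = len(members_bg)
        k = len(query & members_bg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({
            "term_id": tid, "term_name": name,
            "k": k, "K": K, "n": n, "N": N,
            "query_fraction": k / n if n else 0.0,
            "p_value": min(p, 1.0),
        })
    result = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    m_tested = len(result)
    result["p_bonferroni"] = (result["p_value"] * m_tested).clip(upper=1.0)
    return result.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
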