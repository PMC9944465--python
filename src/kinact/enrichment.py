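"""Pathway over-representation analysis against local gene-set collections.

One-sided hypergeometric test per pathway (the STRING/clusterProfiler
convention): with universe size N, pathway size K, query size n and overlap
k, p = P(X >= k).  Effect size is reported as *strength* =
log10(observed/expected) with expected = n*K/N, and *gene ratio* =
observed/query size, the two columns the STRING and Reactome-style reports
print.  Results carry Benjamini-Hochberg q-values across all tested
pathways.

The default universe is every gene in the loaded collection; both strength
and p depend on this choice, so an explicit universe (e.g. the proteins on
the array design) can be passed instead.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy import stats

from .io import PathwayCollection
from .profiling import bh_fdr

__all__ = ["overrepresentation_test", "enrichment_table", "strength"]


def overrepresentation_test(
    query: set[str], pathway: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric p for the query/pathway overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not pathway <= universe or not query <= universe:
        raise ValueError("pathway and query must be subsets of the universe")
    N, K, n = len(universe), len(pathway), len(query)
    observed = len(query & pathway)
    p = float(stats.hypergeom.sf(observed - 1, N, K, n))
    return observed, min(1.0, p)


def strength(observed: int, background: int, query_size: int, universe_size: int) -> float:
    """log10(observed/expected), expected = query_size * background / universe_size."""
    expected = query_size * background / universe_size
    if observed == 0:
        return -math.inf
    return math.log10(observed / expected)


def enrichment_table(
    query: set[str],
    pathways: PathwayCollection,
    p_cutoff: float = 0.05,
    universe: set[str] | None = None,
    top: int | None = 20,
) -> pd.DataFrame:
    """One record per pathway, sorted by q then p; top-k rows when ``top`` set.

    Query identifiers outside the universe are dropped before testing; a
    query entirely unmapped is an error naming the offending identifiers.
    """
    uni = set(universe) if universe is not None else set(pathways.universe)
    mapped = set(query) & uni
    if not mapped:
        raise ValueError(f"query has no identifiers in the universe: {sorted(query)[:10]}")
    rows = []
    for pid, (desc, members) in pathways.pathways.items():
        mem = set(members) & uni
        if not mem:
            continue
        observed, p = overrepresentation_test(mapped, mem, uni)
        rows.append(
            {
                "pathway_id": pid,
                "description": desc,
                "observed": observed,
                "background": len(mem),
                "query_size": len(mapped),
                "universe_size": len(uni),
                "p_value": p,
                "strength": strength(observed, len(mem), len(mapped), len(uni)),
                "gene_ratio": observed / len(mapped),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < p_cutoff
    out = out.sort_values(["q_value", "p_value", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )
    if top is not None:
        out = out.head(top)
    return out
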