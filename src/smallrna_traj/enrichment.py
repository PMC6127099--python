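"""Term enrichment of gene sets by the hypergeometric upper-tail test.

Replaces service-based functional annotation with the transparent exact
test: for a query of n genes from a universe of N, a term covering K genes
and overlapping the query in k, p = P(X >= k) under sampling without
replacement. p values are BH-adjusted across all tested terms.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def load_term_map(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns term_id, term_label, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"term_id", "term_label", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"term map lacks columns: {sorted(missing)}")
    return df


def hypergeom_enrich(
    query: Iterable[str],
    term_map: pd.DataFrame,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``query`` per term.

    Term gene sets are restricted to the universe; query genes outside the
    universe raise an error naming the offenders. Terms are reported in
    sorted term-id order with BH-adjusted p values and an ``enriched`` flag
    at ``alpha``.
    """
    query_set = set(query)
    universe_set = set(universe)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValueError(f"query genes outside universe: {offenders}")
    N, n = len(universe_set), len(query_set)
    rows = []
    for term_id, sub in sorted(term_map.groupby("term_id")):
        genes = set(sub["gene_id"]) & universe_set
        K = len(genes)
        k = len(genes & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term_id": term_id,
                "term_label": sub["term_label"].iloc[0],
                "overlap": k,
                "term_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_label",
            "overlap",
            "term_size",
            "query_size",
            "universe_size",
            "p",
        ],
    )
    result["q"] = bh_adjust(result["p"]) if len(result) else []
    result["enriched"] = result["q"] < alpha
    return result
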