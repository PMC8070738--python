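"""Hypergeometric over/under-representation of annotation terms.

Given a flat gene→term annotation restricted to the universe of quantified
genes, each term is tested for enrichment or depletion in a query gene set
with exact hypergeometric tail probabilities:

    p_over  = P(X >= k),  p_under = P(X <= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term size within the universe, n the
query size and k the observed overlap.  The smaller tail (one-sided, in the
more extreme direction) is adjusted across terms with Benjamini–Hochberg or
Holm–Bonferroni, and a direction is assigned when the adjusted value clears
alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AnnotationTable:
    """term_id → member gene set, restricted to a universe of genes.

    Terms left with zero members after restriction are dropped with a
    logged warning.
    """

    terms: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_frame(cls, annot: pd.DataFrame, universe: set[str]) -> "AnnotationTable":
        """Build from a two-column (gene_id, term_id) table."""
        terms: dict[str, set[str]] = {}
        for term, grp in annot.groupby("term_id"):
            members = set(grp["gene_id"]) & universe
            if not members:
                logger.warning("term %s has no genes in universe; dropped", term)
                continue
            terms[term] = members
        return cls(terms=terms, universe=set(universe))


def enrich(
    query: set[str],
    annot: AnnotationTable,
    correction: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact hypergeometric enrichment/depletion of every term in a query set.

    Query genes outside the universe are dropped with a warning.  Returns a
    per-term table with columns K (term size), n (query size), k (overlap),
    p_over, p_under, p_raw (smaller tail), p_adj and direction
    ∈ {enriched, depleted, ns}.
    """
    if not annot.universe:
        raise ValueError("empty universe")
    outside = set(query) - annot.universe
    if outside:
        logger.warning("%d query gene(s) outside universe dropped", len(outside))
    query = set(query) & annot.universe
    if not query:
        raise ValueError("empty query set after restriction to universe")

    n_universe = len(annot.universe)
    n_query = len(query)
    rows = []
    for term, members in sorted(annot.terms.items()):
        big_k = len(members)
        k = len(members & query)
        dist = hypergeom(n_universe, big_k, n_query)
        p_over = float(dist.sf(k - 1))
        p_under = float(dist.cdf(k))
        rows.append((term, big_k, n_query, k, p_over, p_under))
    table = pd.DataFrame(
        rows, columns=["term_id", "K", "n", "k", "p_over", "p_under"]
    ).set_index("term_id")

    table["p_raw"] = table[["p_over", "p_under"]].min(axis=1)
    method = {"bh": "fdr_bh", "holm": "holm"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r} (use 'bh' or 'holm')")
    table["p_adj"] = multipletests(table["p_raw"], method=method)[1]

    expected = table["K"] * n_query / n_universe
    direction = pd.Series("ns", index=table.index, dtype=object)
    sig = table["p_adj"] < alpha
    direction[sig & (table["p_over"] <= table["p_under"])] = "enriched"
    direction[sig & (table["p_over"] > table["p_under"])] = "depleted"
    table["fold_enrichment"] = table["k"] / expected
    table["direction"] = direction
    return table
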