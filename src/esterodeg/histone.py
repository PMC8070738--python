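"""Histone-modification enrichment in differentially expressed gene sets.

Each gene carries a vector of ChIP co-immunoprecipitation ratios for a set
of histone modifications (by default 3 acetylations and 5 methylations).
For each modification, the ratios of the up- and downregulated gene classes
are compared to those of non-significant genes with a two-group
Kruskal–Wallis rank test (equivalent to a rank-sum test for two groups),
Benjamini–Hochberg-adjusted across all class × modification tests.  The
fold enrichment is the ratio of the class mean to the non-significant mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _kw_two_group(x: np.ndarray, y: np.ndarray) -> float:
    """Two-group Kruskal–Wallis p; 1.0 when all values tie."""
    try:
        return float(stats.kruskal(x, y).pvalue)
    except ValueError:  # all numbers identical
        return 1.0


def histone_enrich(
    table: pd.DataFrame,
    gene_classes: pd.Series,
    alpha: float = 0.05,
    classes: tuple[str, ...] = ("up", "down"),
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Per-(class, modification) enrichment vs non-significant genes.

    Parameters
    ----------
    table
        Genes × modifications ratio table; missing values allowed and
        dropped per modification, not per gene.
    gene_classes
        gene_id → class in {"up", "down", "ns"}; must cover the table's
        genes and provide a nonempty "ns" reference class.

    Returns
    -------
    (results, summary)
        ``results`` has one row per class × modification with the class and
        reference means, fold enrichment, raw and adjusted p and a call in
        {enriched, depleted, ns}.  ``summary`` counts enriched/depleted
        modifications per class ("x of 8"-style).
    """
    gene_classes = gene_classes.reindex(table.index)
    if gene_classes.isna().any():
        missing = list(table.index[gene_classes.isna()])[:5]
        raise ValueError(f"genes without class label: {missing}")
    bad = set(gene_classes.unique()) - {"up", "down", "ns"}
    if bad:
        raise ValueError(f"unknown gene class(es): {sorted(bad)}")
    ns_genes = table.index[gene_classes == "ns"]
    if len(ns_genes) == 0:
        raise ValueError("empty non-significant reference set")

    rows = []
    for cls in classes:
        cls_genes = table.index[gene_classes == cls]
        for mod in table.columns:
            ref = table.loc[ns_genes, mod].dropna().to_numpy(dtype=float)
            grp = table.loc[cls_genes, mod].dropna().to_numpy(dtype=float)
            if len(grp) == 0 or len(ref) == 0:
                rows.append((cls, mod, np.nan, np.nan, np.nan, np.nan))
                continue
            p = _kw_two_group(grp, ref)
            rows.append((cls, mod, grp.mean(), ref.mean(),
                         grp.mean() / ref.mean() if ref.mean() != 0 else np.nan, p))
    res = pd.DataFrame(
        rows,
        columns=["gene_class", "modification", "mean_ratio_class",
                 "mean_ratio_ns", "fold_enrichment", "p_raw"],
    )

    tested = res["p_raw"].notna()
    res["p_adj"] = np.nan
    if tested.any():
        res.loc[tested, "p_adj"] = multipletests(
            res.loc[tested, "p_raw"], method="fdr_bh"
        )[1]

    call = pd.Series("ns", index=res.index, dtype=object)
    sig = tested & (res["p_adj"] < alpha)
    call[sig & (res["fold_enrichment"] > 1)] = "enriched"
    call[sig & (res["fold_enrichment"] < 1)] = "depleted"
    res["call"] = call

    summary = {
        cls: {
            "enriched": int(((res["gene_class"] == cls) & (call == "enriched")).sum()),
            "depleted": int(((res["gene_class"] == cls) & (call == "depleted")).sum()),
            "n_modifications": int((res["gene_class"] == cls).sum()),
        }
        for cls in classes
    }
    return res, summary
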