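"""Count normalization and differential expression calling.

The expression pipeline mirrors a classical two-strain bulk RNA-seq
comparison: gene-level read counts are normalized to RPKM (reads per
kilobase of transcript per million mapped reads), counts of overlapping
ORFs are corrected by subtracting reads attributable to the shared region,
and per-gene group comparisons are gated by a Brown–Forsythe (Levene) test
of equal variances — homoscedastic genes go through one-way ANOVA,
heteroscedastic genes through a Kruskal–Wallis rank test.  Raw p-values are
adjusted across all tested genes (Benjamini–Hochberg by default) and a gene
is called differentially expressed only under the dual criterion
adjusted p < alpha AND |log2 fold change| >= log2(fc_threshold).

The per-gene statistics are computed vectorized across genes; unit tests
verify each branch against the corresponding scipy.stats routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: pseudo-count (RPKM units) added to both group means before the fold
#: change, so knocked-out genes get a large finite negative log2fc.
RPKM_PSEUDOCOUNT = 0.1

#: significance level of the Brown–Forsythe homoscedasticity gate.
LEVENE_ALPHA = 0.05


@dataclass
class CountMatrix:
    """Integer gene × sample read counts with lengths and a design map.

    ``design`` maps each sample id to its strain label; exactly the samples
    of ``counts`` must be mapped.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    design: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"genes without length annotation: {sorted(missing)[:5]}")
        if (self.gene_lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        unmapped = set(self.counts.columns) - set(self.design)
        if unmapped:
            raise ValueError(f"samples missing from design: {sorted(unmapped)}")

    @property
    def strains(self) -> list[str]:
        """Strain labels in order of first appearance in the sample columns."""
        seen: list[str] = []
        for s in self.counts.columns:
            lab = self.design[s]
            if lab not in seen:
                seen.append(lab)
        return seen

    def samples_of(self, strain: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == strain]


def rpkm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total_counts[s]).
    Per-sample scale invariant: multiplying a sample's counts by k leaves
    that sample's RPKM column unchanged.
    """
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    lengths = cm.gene_lengths.loc[cm.counts.index].to_numpy(dtype=float)
    vals = cm.counts.to_numpy(dtype=float) * 1e9 / (
        lengths[:, None] * totals.to_numpy(dtype=float)[None, :]
    )
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def subtract_overlap(cm: CountMatrix, region_counts: pd.DataFrame) -> CountMatrix:
    """Replace each overlap partner's naive total with its unique-region count.

    ``region_counts`` carries, per declared pair and per sample, the reads
    mapping to the A-unique, B-unique and shared regions (rows ``a_unique``,
    ``b_unique`` and ``shared``; see the synthetic generator and the TSV
    reader).  Genes not in any declared pair are untouched.
    """
    required = {"gene_a", "gene_b", "region"}
    if not required <= set(region_counts.columns):
        raise ValueError(f"region_counts must have columns {sorted(required)}")
    new_counts = cm.counts.copy()
    samples = list(cm.counts.columns)
    for (a, b), grp in region_counts.groupby(["gene_a", "gene_b"], sort=False):
        regions = dict(zip(grp["region"], grp[samples].to_numpy().tolist()))
        for need in ("a_unique", "b_unique", "shared"):
            if need not in regions:
                raise ValueError(
                    f"missing region counts '{need}' for overlap pair ({a}, {b})"
                )
        for gene, reg in ((a, "a_unique"), (b, "b_unique")):
            if gene not in new_counts.index:
                raise ValueError(f"overlap gene {gene!r} not in count matrix")
            corrected = np.asarray(regions[reg], dtype=np.int64)
            naive = new_counts.loc[gene].to_numpy()
            new_counts.loc[gene] = np.minimum(corrected, naive)
    return CountMatrix(counts=new_counts, gene_lengths=cm.gene_lengths, design=cm.design)


@dataclass
class DEGResult:
    """Per-gene table plus summary counts from :func:`deg_test`."""

    table: pd.DataFrame
    summary: dict[str, int] = field(default_factory=dict)


def _one_way_f(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA F and p for two groups (rows = genes)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    n = n1 + n2
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / n
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / (n - 2))
    p = np.where(
        ssw > 0,
        stats.f.sf(np.where(ssw > 0, f, 0.0), 1, n - 2),
        np.where(ssb > 0, 0.0, 1.0),  # zero within-group scatter
    )
    f = np.where(ssw > 0, f, np.where(ssb > 0, np.inf, 0.0))
    return f, p


def _brown_forsythe_p(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Median-centred Levene test p-value, vectorized over genes."""
    z1 = np.abs(x1 - np.median(x1, axis=1, keepdims=True))
    z2 = np.abs(x2 - np.median(x2, axis=1, keepdims=True))
    _, p = _one_way_f(z1, z2)
    return p


def _tie_correction(values: np.ndarray) -> np.ndarray:
    """Kruskal–Wallis tie correction 1 - sum(t^3 - t) / (N^3 - N) per row."""
    n = values.shape[1]
    s = np.sort(values, axis=1)
    # ties form runs in the sorted rows; t^3 - t vanishes for singletons
    corr = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(s[i], return_counts=True)
        corr[i] = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return corr


def _kruskal_wallis(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group Kruskal–Wallis H and p with tie correction."""
    n1, n2 = x1.shape[1], x2.shape[1]
    n = n1 + n2
    x = np.concatenate([x1, x2], axis=1)
    ranks = stats.rankdata(x, axis=1)
    r1 = ranks[:, :n1].mean(axis=1)
    r2 = ranks[:, n1:].mean(axis=1)
    h = (12.0 / (n * (n + 1))) * (
        n1 * (r1 - (n + 1) / 2.0) ** 2 + n2 * (r2 - (n + 1) / 2.0) ** 2
    )
    corr = _tie_correction(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(corr > 0, h / corr, 0.0)
    p = np.where(corr > 0, stats.chi2.sf(h, 1), 1.0)
    return h, p


def deg_test(
    rpkm: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    correction: str = "bh",
    control: str | None = None,
    log_values: bool = False,
    levene_alpha: float = LEVENE_ALPHA,
    pseudocount: float = RPKM_PSEUDOCOUNT,
) -> DEGResult:
    """Levene-gated ANOVA / Kruskal–Wallis differential-expression caller.

    Parameters
    ----------
    rpkm
        Normalized expression, genes × samples.
    design
        Sample → strain map with exactly two strains, each with >= 2
        replicates.
    control
        Strain treated as the reference (wildtype) in the fold change
        log2(mutant / control); defaults to the first strain encountered
        in the sample columns.
    log_values
        Run the group tests on log2(rpkm + pseudocount) instead of raw RPKM.

    Returns
    -------
    DEGResult
        ``table`` has one row per gene: mean RPKM per strain, log2fc,
        test_used ∈ {anova, kruskal_wallis, none}, p_raw, p_adj and
        deg_class ∈ {up, down, ns, untested}; ``summary`` counts
        n_tested / n_up / n_down / n_ns.
    """
    strains: list[str] = []
    for s in rpkm.columns:
        if s not in design:
            raise ValueError(f"sample {s!r} missing from design")
        if design[s] not in strains:
            strains.append(design[s])
    if len(strains) != 2:
        raise ValueError(f"exactly two strains required, got {strains}")
    if control is None:
        control = strains[0]
    elif control not in strains:
        raise ValueError(f"unknown control strain {control!r}")
    treat = next(s for s in strains if s != control)

    cols_c = [s for s in rpkm.columns if design[s] == control]
    cols_t = [s for s in rpkm.columns if design[s] == treat]
    if min(len(cols_c), len(cols_t)) < 2:
        raise ValueError("each strain needs at least 2 replicates")

    xc = rpkm[cols_c].to_numpy(dtype=float)
    xt = rpkm[cols_t].to_numpy(dtype=float)
    mean_c, mean_t = xc.mean(axis=1), xt.mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))

    detected = (xc.sum(axis=1) + xt.sum(axis=1)) > 0
    var_c = xc.var(axis=1)
    var_t = xt.var(axis=1)
    degenerate = (var_c == 0) & (var_t == 0) & (mean_c == mean_t)
    testable = detected & ~degenerate

    yc, yt = xc, xt
    if log_values:
        yc = np.log2(xc + pseudocount)
        yt = np.log2(xt + pseudocount)

    p_lev = _brown_forsythe_p(yc, yt)
    hetero = p_lev < levene_alpha
    _, p_anova = _one_way_f(yc, yt)
    _, p_kw = _kruskal_wallis(yc, yt)

    p_raw = np.where(hetero, p_kw, p_anova)
    test_used = np.where(hetero, "kruskal_wallis", "anova").astype(object)
    test_used[~testable] = "none"
    p_raw = np.where(testable, p_raw, np.nan)

    p_adj = np.full_like(p_raw, np.nan)
    if testable.any():
        method = {"bh": "fdr_bh", "holm": "holm"}.get(correction)
        if method is None:
            raise ValueError(f"unknown correction {correction!r} (use 'bh' or 'holm')")
        p_adj[testable] = multipletests(p_raw[testable], method=method)[1]

    lfc_cut = np.log2(fc_threshold)
    deg_class = np.full(len(rpkm), "untested", dtype=object)
    deg_class[testable] = "ns"
    sig = testable & (p_adj < alpha) & (np.abs(log2fc) >= lfc_cut)
    deg_class[sig & (log2fc > 0)] = "up"
    deg_class[sig & (log2fc < 0)] = "down"

    table = pd.DataFrame(
        {
            f"rpkm_mean_{control}": mean_c,
            f"rpkm_mean_{treat}": mean_t,
            "log2fc": log2fc,
            "test_used": test_used,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "deg_class": deg_class,
        },
        index=rpkm.index,
    )
    summary = {
        "n_tested": int(testable.sum()),
        "n_up": int((deg_class == "up").sum()),
        "n_down": int((deg_class == "down").sum()),
        "n_ns": int((deg_class == "ns").sum()),
    }
    return DEGResult(table=table, summary=summary)
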