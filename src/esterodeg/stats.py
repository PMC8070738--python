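"""Metabolite-comparison and sensory statistics.

Covers the statistical toolkit of a wine-fermentation phenotyping study:

* control normalization — each compound's values divided by the mean of
  the control strain, so the control's relative mean is 1;
* Kruskal–Wallis omnibus with a rank-based Fisher-LSD post hoc vs the
  control group, Benjamini–Hochberg-corrected (the ``agricolae``-style
  procedure);
* two-way ANOVA (strain × must) on a linear model with Tukey HSD post hoc
  for significant effects;
* the triangular (forced-choice) sensory discrimination test: one-sided
  exact binomial with chance level 1/3;
* Wilcoxon comparison of descriptor intensities between two wines, paired
  (signed-rank over judges) by default or unpaired (rank-sum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


def normalize_by_control(
    values: pd.Series, groups: pd.Series, control_label: str, name: str = "compound"
) -> pd.Series:
    """Divide every value by the mean of the control group's values."""
    mask = groups == control_label
    if not mask.any():
        raise ValueError(f"no replicates for control group {control_label!r}")
    m = values[mask].mean()
    if m == 0:
        raise ValueError(f"zero control mean for {name!r}")
    return values / m


@dataclass
class KWLSDResult:
    """Omnibus Kruskal–Wallis plus rank-LSD comparisons vs control."""

    h_statistic: float
    p_omnibus: float
    comparisons: pd.DataFrame  # group, mean_rank_diff, t, p_raw, p_adj, significant


def kw_lsd(
    values: pd.Series,
    groups: pd.Series,
    control_label: str,
    alpha: float = 0.01,
) -> KWLSDResult:
    """Kruskal–Wallis omnibus + rank-based Fisher-LSD vs the control group.

    All observations are ranked jointly; each non-control group's mean rank
    is compared to the control's with the LSD criterion

        t = (Rbar_i - Rbar_c) / sqrt(S2 * (N - 1 - H) / (N - k) * (1/n_i + 1/n_c))

    where S2 is the variance of the ranks and H the tie-corrected
    Kruskal–Wallis statistic; p-values come from a t distribution with
    N - k df and are BH-adjusted across the comparisons.  Two groups of
    constant, equal values yield an omnibus p of 1 by convention.
    """
    levels = [g for g in pd.unique(groups) if g != control_label]
    if control_label not in set(groups):
        raise ValueError(f"control group {control_label!r} absent")
    if not levels:
        raise ValueError("need at least one non-control group")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 replicates")

    x = values.to_numpy(dtype=float)
    n_total = len(x)
    k = len(levels) + 1
    ranks = stats.rankdata(x)
    rser = pd.Series(ranks, index=groups.values)

    if np.all(x == x[0]):
        h, p_omni = 0.0, 1.0
    else:
        arrays = [values[groups == g].to_numpy() for g in [control_label, *levels]]
        h, p_omni = stats.kruskal(*arrays)

    s2 = (np.sum(ranks ** 2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1) \
        if n_total > 1 else 0.0
    df = n_total - k
    rbar_c = rser.loc[control_label].mean()
    n_c = counts[control_label]

    rows = []
    for g in levels:
        rbar_g = rser.loc[g].mean()
        diff = rbar_g - rbar_c
        se2 = s2 * max(n_total - 1 - h, 0.0) / df * (1.0 / counts[g] + 1.0 / n_c) \
            if df > 0 else 0.0
        if se2 > 0:
            t = diff / np.sqrt(se2)
            p = 2.0 * stats.t.sf(abs(t), df)
        else:
            t, p = 0.0, 1.0
        rows.append((g, diff, t, p))
    comp = pd.DataFrame(rows, columns=["group", "mean_rank_diff", "t", "p_raw"])
    comp["p_adj"] = multipletests(comp["p_raw"], method="fdr_bh")[1]
    comp["significant"] = comp["p_adj"] < alpha
    return KWLSDResult(h_statistic=float(h), p_omnibus=float(p_omni), comparisons=comp)


@dataclass
class TwoWayANOVAResult:
    """Effect table and post-hoc comparisons of a strain × must ANOVA."""

    effects: pd.DataFrame          # sum_sq, df, F, PR(>F) per effect
    testable: bool
    hsd: dict[str, pd.DataFrame]   # factor -> Tukey HSD table (significant effects)


def anova2_hsd(
    values: pd.Series,
    strain: pd.Series,
    must: pd.Series,
    alpha: float = 0.001,
    hsd_alpha: float = 0.05,
) -> TwoWayANOVAResult:
    """Two-way ANOVA with interaction plus Tukey HSD for significant effects.

    Effects are strain, must and strain:must on a linear model (type-II
    sums of squares, which coincide with the classical decomposition for
    balanced designs).  All-constant responses are reported untestable.
    """
    for fac, name in ((strain, "strain"), (must, "must")):
        if fac.nunique() < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
    cells = pd.crosstab(strain, must)
    if (cells == 0).any().any():
        raise ValueError("empty strain x must cell: interaction not estimable")

    df = pd.DataFrame({"value": values.to_numpy(dtype=float),
                       "strain": strain.to_numpy(), "must": must.to_numpy()})
    if np.all(df["value"] == df["value"].iloc[0]):
        empty = pd.DataFrame(columns=["sum_sq", "df", "F", "PR(>F)"])
        return TwoWayANOVAResult(effects=empty, testable=False, hsd={})

    model = ols("value ~ C(strain) + C(must) + C(strain):C(must)", data=df).fit()
    effects = anova_lm(model, typ=2)
    effects = effects.rename(index={
        "C(strain)": "strain", "C(must)": "must",
        "C(strain):C(must)": "strain:must",
    })

    hsd: dict[str, pd.DataFrame] = {}
    for factor in ("strain", "must"):
        if effects.loc[factor, "PR(>F)"] < alpha:
            res = pairwise_tukeyhsd(df["value"], df[factor], alpha=hsd_alpha)
            hsd[factor] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
    return TwoWayANOVAResult(effects=effects, testable=True, hsd=hsd)


def triangular_test(n_trials: int, n_correct: int) -> float:
    """One-sided exact binomial p of a triangular discrimination test.

    Under the null of no perceptible difference each answer is correct with
    probability 1/3; p = P(X >= n_correct), X ~ Binomial(n_trials, 1/3).
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError("need 0 <= n_correct <= n_trials")
    return float(stats.binomtest(n_correct, n_trials, 1.0 / 3.0,
                                 alternative="greater").pvalue)


def descriptor_wilcoxon(
    ratings: pd.DataFrame,
    alpha: float = 0.05,
    paired: bool = True,
) -> pd.DataFrame:
    """Per-descriptor Wilcoxon comparison of two wines.

    ``ratings`` is tidy with columns (judge, wine, descriptor, intensity)
    and exactly two wines.  Paired mode runs the signed-rank test over the
    per-judge differences (zero differences dropped; identical vectors are
    reported not-significant with p = 1); unpaired mode runs the two-sample
    rank-sum (Mann–Whitney) test.  Exact p-values are used at small n.
    """
    required = {"judge", "wine", "descriptor", "intensity"}
    if not required <= set(ratings.columns):
        raise ValueError(f"ratings must have columns {sorted(required)}")
    wines = list(pd.unique(ratings["wine"]))
    if len(wines) != 2:
        raise ValueError(f"exactly two wines required, got {wines}")
    w1, w2 = wines

    rows = []
    for desc, grp in ratings.groupby("descriptor", sort=False):
        pivot = grp.pivot_table(index="judge", columns="wine", values="intensity")
        if paired:
            pivot = pivot.dropna()
            if len(pivot) < 5:
                raise ValueError(
                    f"descriptor {desc!r}: paired mode needs >= 5 judges rating both wines"
                )
            d = pivot[w1].to_numpy() - pivot[w2].to_numpy()
            if np.all(d == 0):
                rows.append((desc, len(pivot), np.nan, 1.0, False))
                continue
            res = stats.wilcoxon(d, zero_method="wilcox", method="auto")
            rows.append((desc, len(pivot), float(res.statistic), float(res.pvalue),
                         res.pvalue < alpha))
        else:
            a = grp.loc[grp["wine"] == w1, "intensity"].dropna().to_numpy()
            b = grp.loc[grp["wine"] == w2, "intensity"].dropna().to_numpy()
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            rows.append((desc, len(a) + len(b), float(res.statistic),
                         float(res.pvalue), res.pvalue < alpha))
    return pd.DataFrame(
        rows, columns=["descriptor", "n", "statistic", "p_value", "significant"]
    )
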