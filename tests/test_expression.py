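"""Unit and property tests for RPKM, overlap subtraction and the DEG caller."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from esterodeg import (
    CountMatrix, CountSimSpec, deg_test, rpkm_normalize, simulate_counts,
    subtract_overlap,
)
from esterodeg.expression import (
    _brown_forsythe_p, _kruskal_wallis, _one_way_f,
)


class TestRPKM:
    def test_unit_scale_case(self):
        """10 reads on a 1 kb gene in a 1e6-read library give RPKM 10."""
        counts = pd.DataFrame({"s1": [10, 999_990]}, index=["g1", "filler"])
        cm = CountMatrix(
            counts=counts,
            gene_lengths=pd.Series([1000, 10_000], index=counts.index),
            design={"s1": "wt"},
        )
        assert rpkm_normalize(cm).loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_counts_zero_rpkm(self, small_count_matrix):
        assert rpkm_normalize(small_count_matrix).loc["gB"].eq(0).all()

    def test_matches_per_cell_formula(self, rng):
        """Random 20x4 matrix equals independent per-cell recomputation."""
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 3000, 20), index=counts.index)
        cm = CountMatrix(counts=counts, gene_lengths=lengths,
                         design={s: "x" for s in counts.columns})
        got = rpkm_normalize(cm)
        totals = counts.sum(axis=0)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * totals[s])
                assert got.loc[g, s] == pytest.approx(expected)

    def test_per_sample_scale_invariance(self, small_count_matrix):
        """Multiplying one sample's counts by k leaves its RPKM unchanged."""
        base = rpkm_normalize(small_count_matrix)
        scaled_counts = small_count_matrix.counts.copy()
        scaled_counts["wt_1"] *= 7
        cm = CountMatrix(counts=scaled_counts,
                         gene_lengths=small_count_matrix.gene_lengths,
                         design=small_count_matrix.design)
        scaled = rpkm_normalize(cm)
        np.testing.assert_allclose(scaled["wt_1"], base["wt_1"])

    def test_zero_library_names_sample(self, small_count_matrix):
        counts = small_count_matrix.counts.copy()
        counts["wt_2"] = 0
        cm = CountMatrix(counts=counts,
                         gene_lengths=small_count_matrix.gene_lengths,
                         design=small_count_matrix.design)
        with pytest.raises(ValueError, match="wt_2"):
            rpkm_normalize(cm)


class TestSubtractOverlap:
    @staticmethod
    def _regions(samples, a_unique, b_unique, shared):
        return pd.DataFrame(
            [["gA", "gC", "a_unique", *a_unique],
             ["gA", "gC", "b_unique", *b_unique],
             ["gA", "gC", "shared", *shared]],
            columns=["gene_a", "gene_b", "region", *samples],
        )

    def test_zero_shared_is_identity(self, small_count_matrix):
        samples = list(small_count_matrix.counts.columns)
        naive_a = small_count_matrix.counts.loc["gA"].tolist()
        naive_c = small_count_matrix.counts.loc["gC"].tolist()
        regions = self._regions(samples, naive_a, naive_c, [0, 0, 0, 0])
        out = subtract_overlap(small_count_matrix, regions)
        pd.testing.assert_frame_equal(out.counts, small_count_matrix.counts)

    def test_fully_shared_gene_drops_to_zero(self, small_count_matrix):
        """A gene whose naive total is all shared reads is corrected to 0."""
        samples = list(small_count_matrix.counts.columns)
        naive_a = small_count_matrix.counts.loc["gA"].tolist()
        regions = self._regions(samples, [0, 0, 0, 0],
                                small_count_matrix.counts.loc["gC"].tolist(),
                                naive_a)
        out = subtract_overlap(small_count_matrix, regions)
        assert out.counts.loc["gA"].eq(0).all()

    def test_corrected_never_exceeds_naive(self, small_count_matrix):
        samples = list(small_count_matrix.counts.columns)
        regions = self._regions(samples, [999] * 4, [999] * 4, [1] * 4)
        out = subtract_overlap(small_count_matrix, regions)
        assert (out.counts.to_numpy() <= small_count_matrix.counts.to_numpy()).all()

    def test_generator_truth_recovered(self):
        """Corrected counts equal the generator's unique-region truth."""
        sim = simulate_counts(CountSimSpec(n_genes=200, n_up=10, n_down=5, seed=3))
        out = subtract_overlap(sim.counts, sim.region_counts)
        samples = list(sim.counts.counts.columns)
        a = sim.region_counts.iloc[0]["gene_a"]
        b = sim.region_counts.iloc[0]["gene_b"]
        a_unique = sim.region_counts.set_index("region").loc["a_unique", samples]
        b_unique = sim.region_counts.set_index("region").loc["b_unique", samples]
        np.testing.assert_array_equal(out.counts.loc[a], a_unique.astype(int))
        np.testing.assert_array_equal(out.counts.loc[b], b_unique.astype(int))

    def test_missing_region_raises(self, small_count_matrix):
        samples = list(small_count_matrix.counts.columns)
        regions = self._regions(samples, [1] * 4, [1] * 4, [1] * 4)
        regions = regions[regions["region"] != "shared"]
        with pytest.raises(ValueError, match="shared"):
            subtract_overlap(small_count_matrix, regions)


def _kw_exact_p(x, y):
    """Exact 3v3 Kruskal–Wallis p by enumerating all C(6,3) group splits."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(pooled)

    def h_of(idx):
        a = ranks[list(idx)]
        b = ranks[[i for i in range(n) if i not in idx]]
        r1, r2 = a.mean(), b.mean()
        return (12.0 / (n * (n + 1))) * (
            len(a) * (r1 - (n + 1) / 2) ** 2 + len(b) * (r2 - (n + 1) / 2) ** 2
        )

    observed = h_of(range(len(x)))
    hs = [h_of(c) for c in itertools.combinations(range(n), len(x))]
    return np.mean([h >= observed - 1e-12 for h in hs]), observed


class TestDEGTest:
    def _rpkm(self, values):
        """genes x 6 samples table with a 3v3 design."""
        cols = [f"wt_{i}" for i in range(3)] + [f"mut_{i}" for i in range(3)]
        df = pd.DataFrame(values, columns=cols,
                          index=[f"g{i}" for i in range(len(values))])
        design = {c: ("wt" if c.startswith("wt") else "mut") for c in cols}
        return df, design

    def test_constant_gene_untested(self):
        rpkm, design = self._rpkm([[5.0] * 6, [1, 2, 3, 9, 10, 11]])
        res = deg_test(rpkm, design)
        assert res.table.loc["g0", "deg_class"] == "untested"
        assert res.table.loc["g0", "test_used"] == "none"
        assert res.summary["n_tested"] == 1

    def test_all_zero_gene_excluded(self):
        rpkm, design = self._rpkm([[0.0] * 6, [1, 2, 3, 9, 10, 11]])
        res = deg_test(rpkm, design)
        assert res.table.loc["g0", "deg_class"] == "untested"

    def test_bh_monotone_and_at_least_raw(self):
        sim = simulate_counts(CountSimSpec(n_genes=300, n_up=20, n_down=5, seed=7))
        res = deg_test(rpkm_normalize(sim.counts), sim.counts.design)
        t = res.table.dropna(subset=["p_raw"]).sort_values("p_raw")
        assert (t["p_adj"].to_numpy() >= t["p_raw"].to_numpy() - 1e-12).all()
        assert (np.diff(t["p_adj"].to_numpy()) >= -1e-12).all()

    def test_class_counts_partition_tested_genes(self):
        sim = simulate_counts(CountSimSpec(n_genes=300, n_up=20, n_down=5, seed=8))
        res = deg_test(rpkm_normalize(sim.counts), sim.counts.design)
        s = res.summary
        assert s["n_up"] + s["n_down"] + s["n_ns"] == s["n_tested"]

    def test_anova_branch_equals_t_squared(self, rng):
        """On two groups the one-way F statistic equals the pooled t squared."""
        x1 = rng.normal(0, 1, (50, 3))
        x2 = rng.normal(0.5, 1, (50, 3))
        f, _ = _one_way_f(x1, x2)
        for i in range(50):
            t = stats.ttest_ind(x1[i], x2[i]).statistic
            assert f[i] == pytest.approx(t ** 2, rel=1e-10)

    def test_kw_matches_exact_enumeration_3v3(self, rng):
        """On tie-free 3v3 inputs the KW p depends only on the rank split and
        equals the value enumerated over all C(6,3) splits of ranks 1..6."""
        # independent oracle: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
        enum = {}
        for combo in itertools.combinations(range(1, 7), 3):
            r1 = sum(combo)
            r2 = 21 - r1
            h = 12.0 / (6 * 7) * (r1 ** 2 / 3 + r2 ** 2 / 3) - 3 * 7
            enum[frozenset(combo)] = stats.chi2.sf(h, 1)
        for _ in range(10):
            x = rng.normal(0, 1, 3)
            y = rng.normal(1, 1, 3)
            ranks = stats.rankdata(np.concatenate([x, y]))
            key = frozenset(int(r) for r in ranks[:3])
            h_mine, p_mine = _kruskal_wallis(x[None, :], y[None, :])
            assert p_mine[0] == pytest.approx(enum[key], rel=1e-10)
            assert p_mine[0] >= min(enum.values()) - 1e-12  # attainable floor

    def test_kw_minimum_attainable_3v3(self):
        """Perfect 3v3 separation attains the finite KW floor H = 3.857..."""
        h, p = _kruskal_wallis(np.array([[1.0, 2.0, 3.0]]),
                               np.array([[4.0, 5.0, 6.0]]))
        assert h[0] == pytest.approx(27.0 / 7.0, rel=1e-12)
        p_exact, _ = _kw_exact_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p_exact == pytest.approx(2 / 20)  # both extreme splits

    def test_branch_selection_matches_scipy(self, rng):
        """The Levene gate and both branches agree with scipy per gene."""
        sim = simulate_counts(CountSimSpec(n_genes=80, n_up=10, n_down=5,
                                           dispersion=2.0, seed=11))
        rpkm = rpkm_normalize(sim.counts)
        res = deg_test(rpkm, sim.counts.design)
        cols_wt = [c for c in rpkm.columns if c.startswith("wt")]
        cols_mut = [c for c in rpkm.columns if c.startswith("mut")]
        for g in rpkm.index:
            row = res.table.loc[g]
            if row["test_used"] == "none":
                continue
            a = rpkm.loc[g, cols_wt].to_numpy(float)
            b = rpkm.loc[g, cols_mut].to_numpy(float)
            p_lev = stats.levene(a, b, center="median").pvalue
            expected_branch = "kruskal_wallis" if p_lev < 0.05 else "anova"
            assert row["test_used"] == expected_branch
            if expected_branch == "anova":
                ref = stats.f_oneway(a, b).pvalue
            else:
                ref = stats.kruskal(a, b).pvalue
            assert row["p_raw"] == pytest.approx(ref, rel=1e-9)

    def test_planted_effects_recalled_with_correct_sign(self):
        sim = simulate_counts(CountSimSpec(n_genes=2000, n_up=100, n_down=10,
                                           dispersion=100.0, seed=1))
        res = deg_test(rpkm_normalize(subtract_overlap(sim.counts, sim.region_counts)),
                       sim.counts.design)
        truth = sim.truth["planted_class"]
        called = res.table["deg_class"]
        de = truth.isin(["up", "down"])
        hits = de & called.isin(["up", "down"])
        assert hits.sum() / de.sum() >= 0.9
        assert (truth[hits] == called[hits]).all()

    def test_deg_dual_criterion_invariant(self):
        sim = simulate_counts(CountSimSpec(n_genes=500, n_up=40, n_down=10,
                                           dispersion=100.0, seed=2))
        res = deg_test(rpkm_normalize(sim.counts), sim.counts.design)
        deg_rows = res.table[res.table["deg_class"].isin(["up", "down"])]
        assert (deg_rows["p_adj"] < 0.05).all()
        assert (deg_rows["log2fc"].abs() >= 1.0).all()

    def test_too_few_replicates_raises(self):
        rpkm, _ = self._rpkm([[1, 2, 3, 4, 5, 6]])
        design = {c: c for c in rpkm.columns}  # six strains of one sample
        with pytest.raises(ValueError):
            deg_test(rpkm, design)

    def test_unknown_correction_raises(self):
        rpkm, design = self._rpkm([[1, 2, 3, 9, 10, 11]])
        with pytest.raises(ValueError, match="correction"):
            deg_test(rpkm, design, correction="bonferroni")

    def test_holm_correction_more_conservative(self):
        sim = simulate_counts(CountSimSpec(n_genes=400, n_up=30, n_down=5,
                                           dispersion=100.0, seed=5))
        rpkm = rpkm_normalize(sim.counts)
        bh = deg_test(rpkm, sim.counts.design, correction="bh")
        holm = deg_test(rpkm, sim.counts.design, correction="holm")
        tested = bh.table["p_adj"].notna()
        assert (holm.table.loc[tested, "p_adj"]
                >= bh.table.loc[tested, "p_adj"] - 1e-12).all()
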