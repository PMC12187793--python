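"""Differential methylation: count reconstruction rounding, the exact
2x2 test against a hypergeometric-enumeration oracle, BH adjustment
against the step-up formula, fold-change antisymmetry, label-swap
symmetry, top-k ordering and Pearson concordance."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

from m5cscope.diffmeth import (
    differential_table,
    log2fc_methylation,
    pairwise_concordance,
    site_diff_test,
    to_read_counts,
    top_k_sites,
)
from m5cscope.io_model import ValidationError
from conftest import make_site_table

K = "AAAACAAAA"


class TestReadCounts:
    @pytest.mark.parametrize(
        "stoich,cov,expected",
        [
            (0.6, 25, (15, 10)),
            (0.0, 8, (0, 8)),
            (1.0, 8, (8, 0)),
            (0.5, 9, (4, 5)),   # 4.5 rounds half to even
            (0.5, 11, (6, 5)),  # 5.5 rounds half to even
        ],
    )
    def test_rounding_rule(self, stoich, cov, expected):
        assert to_read_counts(stoich, cov) == expected

    def test_counts_sum_to_coverage(self, rng):
        for _ in range(200):
            cov = int(rng.integers(1, 100))
            s = float(rng.random())
            m, u = to_read_counts(s, cov)
            assert m + u == cov and 0 <= m <= cov

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValidationError):
            to_read_counts(0.5, 0)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point masses no
    larger than the observed table's, over the full support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestSiteDiffTest:
    def test_identical_counts_give_p_one(self):
        assert site_diff_test(10, 10, 10, 10) == pytest.approx(1.0)
        assert site_diff_test(1, 7, 1, 7) == pytest.approx(1.0)

    def test_strong_contrast_matches_enumeration(self):
        p = site_diff_test(16, 4, 4, 16)
        assert p == pytest.approx(fisher_oracle(16, 4, 4, 16), rel=1e-9)
        assert p < 0.001

    def test_oracle_sweep_exhaustive_small_tables(self):
        # every 2x2 table with N <= 14
        for n in range(2, 15):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0:
                            continue
                        assert site_diff_test(a, b, c, d) == pytest.approx(
                            fisher_oracle(a, b, c, d), rel=1e-8, abs=1e-12
                        )

    def test_oracle_sweep_random_tables_up_to_60(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 61))
            a = int(rng.integers(0, n - 1))
            b = int(rng.integers(0, n - a - 1))
            c = int(rng.integers(0, n - a - b - 1))
            d = n - a - b - c
            if a + b == 0 or c + d == 0:
                continue
            assert site_diff_test(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-8, abs=1e-12
            )

    def test_ztest_agrees_with_fisher_on_large_counts(self):
        p_f = site_diff_test(160, 40, 40, 160)
        p_z = site_diff_test(160, 40, 40, 160, method="ztest")
        assert p_f < 1e-10 and p_z < 1e-10


class TestLog2FC:
    def test_exact_without_pseudocount(self):
        assert log2fc_methylation(0.8, 0.2, eps=0.0) == pytest.approx(2.0)

    def test_identity_is_zero(self):
        for eps in (0.0, 0.01, 0.1):
            assert log2fc_methylation(0.37, 0.37, eps=eps) == 0.0

    def test_pseudocount_arithmetic(self):
        assert log2fc_methylation(0.8, 0.2, eps=0.01) == pytest.approx(
            np.log2(0.81 / 0.21)
        )

    def test_antisymmetry(self, rng):
        for _ in range(100):
            a, b = rng.random(2)
            assert log2fc_methylation(a, b) == pytest.approx(-log2fc_methylation(b, a))


def bh_oracle(p):
    """Benjamini-Hochberg step-up: p_adj(i) = min_{j >= i} min(1, m p(j)/j)
    over the sorted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def two_condition_tables(rng, n=40, delta=0.0):
    rows_a, rows_b = [], []
    for i in range(n):
        cov = int(rng.integers(10, 60))
        sa = float(np.clip(rng.random(), 0.01, 0.99))
        sb = float(np.clip(sa - delta if i % 2 else sa + delta, 0.0, 1.0))
        rows_a.append((f"t{i}", i, K, cov, sa, 1.0))
        rows_b.append((f"t{i}", i, K, cov, sb, 1.0))
    return make_site_table(rows_a, "A"), make_site_table(rows_b, "B")


class TestDifferentialTable:
    def test_bh_matches_step_up_formula(self, rng):
        ta, tb = two_condition_tables(rng, n=60, delta=0.3)
        diff = differential_table(ta, tb)
        assert np.allclose(diff.df["p_adj"], bh_oracle(diff.df["p"]), atol=1e-12)
        assert (diff.df["p_adj"] >= diff.df["p"] - 1e-15).all()
        assert (diff.df["p_adj"] <= 1.0).all()

    def test_bh_on_known_vector(self):
        # {0.0001, 0.0002, 0.5} with m=3 -> {0.0003, 0.0003, 0.5}
        assert np.allclose(bh_oracle([0.0001, 0.0002, 0.5]), [0.0003, 0.0003, 0.5])

    def test_label_requires_both_cuts(self):
        # strong count evidence but |log2FC| < 1 must stay ns
        ta = make_site_table([("t", 0, K, 2000, 0.60, 1.0)], "A")
        tb = make_site_table([("t", 0, K, 2000, 0.35, 1.0)], "B")
        diff = differential_table(ta, tb)
        row = diff.df.iloc[0]
        assert row.p_adj < 1e-6 and abs(row.log2fc) < 1.0
        assert row.label == "ns"

    def test_swap_exchanges_hyper_and_hypo(self, rng):
        ta, tb = two_condition_tables(rng, n=50, delta=0.4)
        d1 = differential_table(ta, tb)
        d2 = differential_table(tb, ta)
        c1, c2 = d1.label_counts(), d2.label_counts()
        assert c1["hyper"] == c2["hypo"] and c1["hypo"] == c2["hyper"]
        assert np.allclose(
            d1.df.sort_values(["transcript_id", "position"])["log2fc"].to_numpy(),
            -d2.df.sort_values(["transcript_id", "position"])["log2fc"].to_numpy(),
        )

    def test_label_counts_stable_under_row_shuffle(self, rng):
        ta, tb = two_condition_tables(rng, n=50, delta=0.4)
        shuffled = make_site_table(
            [tuple(r)[1:] for _, r in ta.df.sample(frac=1, random_state=7).iterrows()], "A"
        )
        d1 = differential_table(ta, tb)
        d2 = differential_table(shuffled, tb)
        assert d1.label_counts() == d2.label_counts()

    def test_min_coverage_applies_to_both_sides(self):
        ta = make_site_table([("t", 0, K, 7, 0.9, 1.0)], "A")
        tb = make_site_table([("t", 0, K, 50, 0.1, 1.0)], "B")
        assert len(differential_table(ta, tb)) == 0

    def test_empty_join_returns_empty_table(self):
        ta = make_site_table([("t1", 0, K, 10, 0.5, 1.0)], "A")
        tb = make_site_table([("t2", 0, K, 10, 0.5, 1.0)], "B")
        diff = differential_table(ta, tb)
        assert len(diff) == 0 and diff.params.get("empty_join")


class TestTopK:
    def build_diff(self, rng, n=30):
        ta, tb = two_condition_tables(rng, n=n, delta=0.45)
        return differential_table(ta, tb)

    def test_matches_hand_sort(self, rng):
        diff = self.build_diff(rng)
        hyper, hypo, flags = top_k_sites(diff, k=5)
        for lab, got in (("hyper", hyper), ("hypo", hypo)):
            sub = diff.df[diff.df["label"] == lab].copy()
            expected = sorted(
                sub.itertuples(index=False),
                key=lambda r: (r.p_adj, -abs(r.log2fc), r.transcript_id, r.position),
            )[:5]
            assert [r.transcript_id for r in expected] == list(got["transcript_id"])

    def test_short_side_flagged(self, rng):
        diff = self.build_diff(rng)
        hyper, hypo, flags = top_k_sites(diff, k=1000)
        assert flags["hyper"] and flags["hypo"]
        assert len(hyper) == diff.label_counts()["hyper"]

    def test_tie_broken_by_fold_change(self):
        ta = make_site_table(
            [("a", 0, K, 400, 0.9, 1.0), ("b", 0, K, 400, 0.6, 1.0)], "A"
        )
        tb = make_site_table(
            [("a", 0, K, 400, 0.05, 1.0), ("b", 0, K, 400, 0.05, 1.0)], "B"
        )
        diff = differential_table(ta, tb)
        df = diff.df
        # force an exact tie in p_adj, then ranking must use |log2fc|
        df.loc[:, "p_adj"] = 1e-9
        hyper, _, _ = top_k_sites(diff, k=2)
        assert list(hyper["transcript_id"]) == ["a", "b"]


class TestPairwiseConcordance:
    def diff_from_vectors(self, lfc, name):
        rows_a, rows_b = [], []
        for i, v in enumerate(lfc):
            sa = min(max(0.3 * 2.0**v, 0.0), 1.0)
            rows_a.append((f"t{i}", i, K, 30, sa, 1.0))
            rows_b.append((f"t{i}", i, K, 30, 0.3, 1.0))
        return differential_table(
            make_site_table(rows_a, "A"), make_site_table(rows_b, "B"),
            name_a=name, name_b="ref", eps=0.0,
        )

    def test_self_correlation_is_one(self):
        d = self.diff_from_vectors([0.5, -0.5, 1.0, -1.0], "x")
        r, n, disc = pairwise_concordance({"x": d, "y": d})
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert disc.loc["x", "y"] == 0

    def test_perfect_anticorrelation(self):
        d1 = self.diff_from_vectors([1.0, 0.5, -1.0], "x")
        d2 = self.diff_from_vectors([-1.0, -0.5, 1.0], "y")
        r, n, disc = pairwise_concordance({"x": d1, "y": d2})
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert disc.loc["x", "y"] == 3

    def test_matches_covariance_formula(self, rng):
        v1 = list(np.round(rng.uniform(-1, 1, 10), 3))
        v2 = list(np.round(rng.uniform(-1, 1, 10), 3))
        d1 = self.diff_from_vectors(v1, "x")
        d2 = self.diff_from_vectors(v2, "y")
        r, _, _ = pairwise_concordance({"x": d1, "y": d2})
        x = d1.df.sort_values("position")["log2fc"].to_numpy()
        y = d2.df.sort_values("position")["log2fc"].to_numpy()
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)
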