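"""Evaluation statistics against independent oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qnmrbench.stats import (
    kruskal_wallis,
    pca_with_projection,
    precision_cv,
    rank_sum_exact,
    relative_trueness,
    summarize_study,
)


# ---------------------------------------------------------------------------
# brute-force oracles, kept independent of the implementation
# ---------------------------------------------------------------------------

def oracle_rank_sum_p(x, y):
    """Two-sided exact p by direct enumeration over value assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = sps.rankdata(pooled)
    center = n * m / 2.0

    def u_of(subset):
        return ranks[list(subset)].sum() - n * (n + 1) / 2.0

    u_obs = u_of(range(n))
    dev = abs(u_obs - center)
    hits = sum(
        1
        for subset in combinations(range(n + m), n)
        if abs(u_of(subset) - center) >= dev - 1e-12
    )
    return u_obs, hits / comb(n + m, n)


def oracle_kruskal_h(groups):
    """Textbook H formula with tie correction."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - (counts ** 3 - counts).sum() / (N ** 3 - N)
    return h / c if c > 0 else 0.0


class TestPrecisionTrueness:
    def test_cv_worked_example(self):
        assert precision_cv([10, 11, 12]) == pytest.approx(100.0 / 11.0)

    def test_cv_identical_replicates(self):
        assert precision_cv([7.7, 7.7, 7.7]) == 0.0

    def test_cv_needs_two_values(self):
        with pytest.raises(ValueError):
            precision_cv([5.0])

    def test_trueness_signed(self):
        assert relative_trueness([95, 95, 95], 100.0) == pytest.approx(-5.0)
        assert relative_trueness([100, 100, 100], 100.0) == 0.0
        assert relative_trueness([120.53], 100.0) == pytest.approx(20.53)

    def test_scale_invariance(self):
        vals = np.array([9.0, 10.5, 12.0])
        for c in (0.01, 3.0, 1e4):
            assert precision_cv(c * vals) == pytest.approx(precision_cv(vals))
            assert relative_trueness(c * vals, c * 10.0) == pytest.approx(
                relative_trueness(vals, 10.0)
            )


class TestRankSum:
    def test_complete_separation_lattice_value(self):
        x = [1, 2, 3, 4, 5]
        y = [10, 11, 12, 13, 14]
        _, p = rank_sum_exact(x, y)
        assert p == pytest.approx(2.0 / 252.0)

    def test_u_equal_1_lattice_value(self):
        x = [1, 2, 3, 4, 6]
        y = [5, 7, 8, 9, 10]  # exactly one inversion: U = 1
        u, p = rank_sum_exact(x, y)
        assert u == 1.0
        assert p == pytest.approx(4.0 / 252.0)

    def test_identical_samples_p_one(self):
        x = [3.0, 1.0, 2.0, 5.0, 4.0]
        _, p = rank_sum_exact(x, x)
        assert p == 1.0

    def test_p_values_on_2k_over_252_lattice(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=5), rng.normal(size=5)
            _, p = rank_sum_exact(x, y)
            k = p * 252.0
            assert k == pytest.approx(round(k), abs=1e-9)
            assert round(k) % 2 == 0

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(1)
        for n in range(1, 7):
            for m in range(1, 7):
                for trial in range(3):
                    x = rng.integers(0, 6, size=n).astype(float)  # with ties
                    y = rng.integers(0, 6, size=m).astype(float)
                    u_i, p_i = rank_sum_exact(x, y)
                    u_o, p_o = oracle_rank_sum_p(x, y)
                    assert u_i == pytest.approx(u_o)
                    assert p_i == pytest.approx(p_o)

    def test_large_sample_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 40)
        y = rng.normal(0.5, 1.0, 35)
        _, p = rank_sum_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_exact([], [1.0])


class TestKruskalWallis:
    def test_worked_example_h_7_2(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_degenerate_constant_groups(self):
        h, p = kruskal_wallis([[3.0, 3.0], [3.0, 3.0], [3.0]])
        assert h == 0.0 and p == 1.0

    def test_matches_formula_oracle_and_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [
                rng.integers(0, 8, size=rng.integers(2, 6)).astype(float)
                for _ in range(k)
            ]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            h, p = kruskal_wallis(groups)
            assert h == pytest.approx(oracle_kruskal_h(groups), abs=1e-10)
            ref_h, ref_p = sps.kruskal(*groups)
            assert h == pytest.approx(ref_h)
            assert p == pytest.approx(ref_p)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestPcaProjection:
    def _matrix(self, seed=0, n=12, p=6):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 1)) @ rng.normal(size=(1, p))
        X = base + 0.01 * rng.normal(size=(n, p))
        return pd.DataFrame(X, columns=[f"q{i}" for i in range(p)])

    def test_held_out_at_training_mean_projects_to_origin(self):
        M = self._matrix()
        held = M.mean(axis=0)
        out = pca_with_projection(M, held)
        np.testing.assert_allclose(out["projected"].to_numpy(), 0.0, atol=1e-10)

    def test_scores_orthogonal(self):
        M = self._matrix(seed=4)
        out = pca_with_projection(M, M.iloc[0])
        s = out["scores"].to_numpy()
        assert abs(np.dot(s[:, 0], s[:, 1])) < 1e-8

    def test_rank_one_structure_dominates_pc1(self):
        M = self._matrix(seed=5)
        out = pca_with_projection(M, M.mean(axis=0))
        assert out["variance_fractions"][0] > 0.95

    def test_constant_column_dropped(self):
        M = self._matrix(seed=6)
        M["const"] = 1.0
        out = pca_with_projection(M, M.mean(axis=0))
        assert out["dropped_columns"] == ["const"]
        assert "const" not in out["loadings"].index


class TestSummarizeStudy:
    def _fixture_table(self):
        # 2 quantities x 2 operators x 3 replicates, one strategy/sequence
        rows = []
        data = {
            ("A", "op1"): [10.0, 11.0, 12.0],
            ("A", "op2"): [9.0, 10.0, 11.0],
            ("B", "op1"): [200.0, 200.0, 200.0],
            ("B", "op2"): [210.0, 220.0, 230.0],
        }
        for (qty, op), vals in data.items():
            for i, v in enumerate(vals):
                rows.append(
                    dict(quantity=qty, strategy="int_extcal", pulse_sequence="zgpr",
                         operator=op, replicate=i + 1, concentration_uM=v)
                )
        return pd.DataFrame(rows)

    def test_hand_computed_fixture(self):
        table = self._fixture_table()
        truth = {"A": 10.0, "B": 200.0}
        out = summarize_study(table, truth)
        per = out["per_operator"].set_index(["quantity", "operator"])
        assert per.loc[("A", "op1"), "cv_percent"] == pytest.approx(100.0 / 11.0)
        assert per.loc[("A", "op1"), "trueness_percent"] == pytest.approx(10.0)
        assert per.loc[("B", "op1"), "cv_percent"] == 0.0
        agg = out["aggregated"].set_index("quantity")
        assert agg.loc["A", "trueness_mean"] == pytest.approx((10.0 + 0.0) / 2)
        assert agg.loc["A", "n_operators"] == 2

    def test_nd_propagates_as_missing_not_zero(self):
        table = self._fixture_table()
        table.loc[
            (table["quantity"] == "B") & (table["operator"] == "op2"),
            "concentration_uM",
        ] = np.nan
        out = summarize_study(table, {"A": 10.0, "B": 200.0})
        per = out["per_operator"].set_index(["quantity", "operator"])
        assert np.isnan(per.loc[("B", "op2"), "cv_percent"])
        assert np.isnan(per.loc[("B", "op2"), "trueness_percent"])
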