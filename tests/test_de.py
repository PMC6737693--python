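"""Tests for abundance filtering, median-split stratification, DE calling and
clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ernet.de import (
    cluster_heatmap,
    differential_expression,
    filter_low_expression,
    select_top_degs,
    stratify_by_gene,
)
from ernet.synthetic import ExprSimConfig, generate_expression_matrix


def toy_matrix(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    df.index.name = "gene"
    return df


class TestFilter:
    def test_boundary_strictness(self):
        m = toy_matrix({"below": [1.99, 1.99], "at": [2.0, 2.0], "above": [7.3, 7.3]})
        kept = filter_low_expression(m)
        assert list(kept.index) == ["at", "above"]

    def test_toy_means(self):
        m = toy_matrix({"g1": [0.5, 0.5], "g2": [2.0, 2.0], "g3": [7.3, 7.3]})
        assert filter_low_expression(m).shape[0] == 2

    def test_empty_result_warns(self):
        m = toy_matrix({"g1": [0.1, 0.1]})
        with pytest.warns(UserWarning):
            out = filter_low_expression(m)
        assert out.empty

    def test_order_and_samples_preserved(self):
        m = toy_matrix({"b": [5, 5], "a": [3, 3], "c": [1, 1]})
        kept = filter_low_expression(m)
        assert list(kept.index) == ["b", "a"]
        assert list(kept.columns) == list(m.columns)


class TestStratify:
    def test_even_symmetric_case(self):
        m = toy_matrix({"MK": [1.0, 2.0, 3.0, 4.0]})
        g = stratify_by_gene(m, "MK")
        assert g.cutoff_value == 2.5
        assert set(g.high) == {"S2", "S3"} and set(g.low) == {"S0", "S1"}

    def test_ties_go_low(self):
        m = toy_matrix({"MK": [1.0, 2.0, 2.0, 2.0, 5.0]})
        g = stratify_by_gene(m, "MK")
        assert g.cutoff_value == 2.0
        assert list(g.high) == ["S4"] and len(g.low) == 4

    def test_odd_distinct_split(self):
        # odd N with distinct values: median sample joins the low group
        rng = np.random.default_rng(0)
        m = toy_matrix({"MK": rng.permutation(np.arange(101, dtype=float))})
        g = stratify_by_gene(m, "MK")
        assert (len(g.high), len(g.low)) == (50, 51)

    def test_errors(self):
        m = toy_matrix({"MK": [1.0, 2.0]})
        with pytest.raises(KeyError):
            stratify_by_gene(m, "ABSENT")
        with pytest.raises(ValueError):
            stratify_by_gene(toy_matrix({"MK": [1.0]}), "MK")


def welch_oracle(a, b):
    """Textbook Welch t-test: statistic and two-sided p via Welch–Satterthwaite."""
    n1, n2 = len(a), len(b)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, 2.0 * stats.t.sf(abs(t), df)


def make_labeled(values_high, values_low, extra_rows=None):
    n1, n2 = len(values_high), len(values_low)
    row = list(values_high) + list(values_low)
    rows = {"g": row}
    if extra_rows:
        rows.update(extra_rows)
    m = toy_matrix(rows)
    labels = stratify_by_gene(toy_matrix({"MK": [2.0] * n1 + [1.0] * n2}), "MK")
    # reuse the same sample ids
    labels.labels.index = m.columns
    return m, labels


class TestDifferentialExpression:
    def test_null_identity(self):
        m, labels = make_labeled([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        t = differential_expression(m, labels, moderated=False)
        assert t.loc["g", "log2fc"] == 0.0
        assert not t.loc["g", "is_deg"]

    def test_fold_change_boundary_strict(self):
        # log2fc exactly 1 (fold change exactly 2) is excluded however small p
        m, labels = make_labeled([4.0, 4.0, 4.0, 4.0], [3.0, 3.0, 3.0, 3.0],
                                 extra_rows={"h": [4.2, 4.1, 4.3, 4.2, 3.0, 3.1, 2.9, 3.0]})
        t = differential_expression(m, labels, moderated=True)
        assert t.loc["g", "log2fc"] == pytest.approx(1.0)
        assert not t.loc["g", "is_deg"]

    def test_welch_matches_textbook_and_permutation(self):
        hi = [5.1, 4.9, 5.3, 5.0]
        lo = [3.0, 3.2, 2.9, 3.1]
        m, labels = make_labeled(hi, lo)
        t = differential_expression(m, labels, moderated=False)
        t_or, p_or = welch_oracle(np.array(hi), np.array(lo))
        assert t.loc["g", "p"] == pytest.approx(p_or, abs=1e-6)
        assert t.loc["g", "stat"] == pytest.approx(t_or, rel=1e-9)
        # permutation envelope: 1e5 random relabelings of the 8 values
        rng = np.random.default_rng(1)
        pooled = np.array(hi + lo)
        obs = abs(t_or)
        count = 0
        draws = 100_000
        for _ in range(draws):
            perm = rng.permutation(pooled)
            count += abs(welch_oracle(perm[:4], perm[4:])[0]) >= obs
        p_perm = (count + 1) / (draws + 1)
        upper = p_perm + 2.576 * np.sqrt(p_perm * (1 - p_perm) / draws)
        assert t.loc["g", "p"] < upper

    @pytest.mark.parametrize("moderated", [True, False])
    def test_group_swap_negates_lfc_preserves_p(self, moderated):
        cfg = ExprSimConfig(n_genes=300, n_samples=40, n_up_planted=20,
                            n_down_planted=20, low_expr_fraction=0.0, seed=2)
        m, _ = generate_expression_matrix(cfg)
        labels = stratify_by_gene(m, cfg.marker_gene)
        swapped_series = labels.labels.map({"high": "low", "low": "high"})
        swapped = type(labels)(labels=swapped_series, marker_gene=labels.marker_gene,
                               cutoff_value=labels.cutoff_value)
        t1 = differential_expression(m, labels, moderated=moderated)
        t2 = differential_expression(m, swapped, moderated=moderated)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-10)

    def test_filter_stratify_commute(self):
        cfg = ExprSimConfig(n_genes=300, n_samples=50, n_up_planted=10,
                            n_down_planted=10, low_expr_fraction=0.3, seed=4)
        m, _ = generate_expression_matrix(cfg)
        a = stratify_by_gene(filter_low_expression(m), cfg.marker_gene)
        b = stratify_by_gene(m, cfg.marker_gene)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_moderated_converges_to_welch_with_n(self):
        def max_dp(n_samples, seed):
            cfg = ExprSimConfig(n_genes=1000, n_samples=n_samples, n_up_planted=0,
                                n_down_planted=0, low_expr_fraction=0.0, seed=seed)
            m, _ = generate_expression_matrix(cfg)
            labels = stratify_by_gene(m, cfg.marker_gene)
            mod = differential_expression(m, labels, moderated=True)
            wel = differential_expression(m, labels, moderated=False)
            return float(np.abs(mod["p"] - wel["p"]).max())

        small, large = max_dp(20, 42), max_dp(1000, 42)
        assert large < small
        assert large < 0.05

    def test_tiny_group_not_callable(self):
        m = toy_matrix({"MK": [2.0, 1.0, 1.0], "g": [5.0, 1.0, 1.2]})
        labels = stratify_by_gene(m, "MK")
        t = differential_expression(m, labels, moderated=False)
        assert np.isnan(t.loc["g", "p"])
        assert not t.loc["g", "is_deg"]


class TestTopDEGs:
    def _table(self, lfcs, ps=None):
        ps = ps if ps is not None else [1e-9] * len(lfcs)
        t = pd.DataFrame({"log2fc": lfcs, "p": ps},
                         index=[f"g{i}" for i in range(len(lfcs))])
        t["is_deg"] = (t["log2fc"].abs() > 1) & (t["p"] < 0.05)
        t["direction"] = np.where(~t["is_deg"], "none",
                                  np.where(t["log2fc"] > 0, "up", "down"))
        return t

    def test_exhaustion_warns(self):
        t = self._table([2.0, 1.5, 3.0])
        with pytest.warns(UserWarning):
            got = select_top_degs(t, n_up=50, n_down=50)
        assert set(got) == {"g0", "g1", "g2"}

    def test_defaults_give_100(self):
        lfcs = list(np.linspace(1.5, 4, 60)) + list(np.linspace(-4, -1.5, 60))
        got = select_top_degs(self._table(lfcs))
        assert len(got) == 100

    def test_ordering(self):
        t = self._table([2.0, 1.5])
        assert select_top_degs(t, n_up=1, n_down=0) == ["g0"]


class TestClusterHeatmap:
    def test_identical_rows_merge_first_at_zero(self):
        m = toy_matrix({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]})
        res = cluster_heatmap(m, ["a", "b", "c"])
        assert res.row_linkage[0, 2] == 0.0
        assert {int(res.row_linkage[0, 0]), int(res.row_linkage[0, 1])} == {0, 1}

    def test_hand_computed_distances(self):
        # d(r0,r1)=5, d(r0,r2)=1 -> first merge joins rows 0 and 2
        m = toy_matrix({"r0": [0.0, 0.0], "r1": [3.0, 4.0], "r2": [0.0, 1.0]})
        res = cluster_heatmap(m, ["r0", "r1", "r2"])
        assert {int(res.row_linkage[0, 0]), int(res.row_linkage[0, 1])} == {0, 2}
        assert res.row_linkage[0, 2] == pytest.approx(1.0)

    def test_permutation_invariant_heights(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(8, 5))
        m1 = pd.DataFrame(data, index=[f"g{i}" for i in range(8)])
        perm = rng.permutation(8)
        m2 = m1.iloc[perm]
        h1 = np.sort(cluster_heatmap(m1, list(m1.index)).row_linkage[:, 2])
        h2 = np.sort(cluster_heatmap(m2, list(m2.index)).row_linkage[:, 2])
        np.testing.assert_allclose(h1, h2, rtol=1e-12)

    def test_too_small_rejected(self):
        m = toy_matrix({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cluster_heatmap(m, ["a"])
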