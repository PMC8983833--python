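"""Label assembly, predictor importance, p-value transform, combination, rating."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from priormap import combine as c


def _drug_table(rows):
    return pd.DataFrame(
        rows, columns=["gene", "drug", "max_phase", "mechanism", "indication"]
    )


class TestLabels:
    def test_phase_threshold(self):
        table = _drug_table(
            [("A", "d1", 1, "m", "i"), ("B", "d2", 2, "m", "i"), ("C", "d3", 4, "m", "i")]
        )
        labels = c.assemble_labels(table, ["A", "B", "C", "D", "E"], control_ratio=1, seed=0)
        assert labels.positives == {"B", "C"}

    def test_same_seed_reproduces_controls(self):
        table = _drug_table([("A", "d", 3, "m", "i")])
        universe = [f"g{i}" for i in range(100)] + ["A"]
        one = c.assemble_labels(table, universe, control_ratio=10, seed=5)
        two = c.assemble_labels(table, universe, control_ratio=10, seed=5)
        assert one.controls == two.controls

    def test_control_count_and_disjointness(self):
        table = _drug_table([(f"P{i}", f"d{i}", 2, "m", "i") for i in range(5)])
        universe = [f"P{i}" for i in range(5)] + [f"g{i}" for i in range(1000)]
        labels = c.assemble_labels(table, universe, control_ratio=10, seed=1)
        assert len(labels.controls) == 50
        assert not labels.positives & labels.controls

    def test_universe_too_small_rejected(self):
        table = _drug_table([("A", "d", 2, "m", "i")])
        with pytest.raises(ValueError, match="too small"):
            c.assemble_labels(table, ["A", "B"], control_ratio=10, seed=0)


class TestImportance:
    def _matrix_and_labels(self, rng, n=500):
        genes = [f"g{i}" for i in range(n)]
        y = rng.random(n) < 0.3
        matrix = pd.DataFrame(
            {
                "nGene": y + 0.01 * rng.standard_normal(n),  # near-perfect feature
                "noise": rng.random(n),
                "weak": 0.3 * y + rng.random(n),
            },
            index=genes,
        )
        labels = c.LabelSet(
            frozenset(g for g, v in zip(genes, y) if v),
            frozenset(g for g, v in zip(genes, y) if not v),
            0,
        )
        return matrix, labels

    def test_perfect_feature_has_largest_importance(self, rng):
        matrix, labels = self._matrix_and_labels(rng)
        table = c.predictor_importance(matrix, labels, n_trees=100, seed=0)
        assert table.importances.idxmax() == "nGene"

    def test_noise_importance_near_zero(self, rng):
        matrix, labels = self._matrix_and_labels(rng)
        table = c.predictor_importance(matrix, labels, n_trees=500, seed=0)
        assert abs(table.importances["noise"]) < 0.02

    def test_row_permutation_invariance(self, rng):
        matrix, labels = self._matrix_and_labels(rng, n=100)
        shuffled = matrix.iloc[rng.permutation(len(matrix))]
        a = c.predictor_importance(matrix, labels, n_trees=50, seed=3)
        b = c.predictor_importance(shuffled, labels, n_trees=50, seed=3)
        pd.testing.assert_series_equal(a.importances, b.importances)

    def test_constant_column_warns(self, rng):
        matrix, labels = self._matrix_and_labels(rng, n=100)
        matrix["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            table = c.predictor_importance(matrix, labels, n_trees=20, seed=0)
        assert table.importances["flat"] == 0.0


class TestSelectInformative:
    def test_rule_application(self):
        table = c.ImportanceTable(pd.Series({"nGene": 0.05, "cA": 0.06, "eB": 0.01}))
        assert c.select_informative(table) == ["nGene", "cA"]

    def test_all_below_baseline_keeps_baseline_only(self):
        table = c.ImportanceTable(pd.Series({"nGene": 0.05, "cA": 0.01}))
        assert c.select_informative(table) == ["nGene"]

    def test_tie_with_baseline_kept(self):
        table = c.ImportanceTable(pd.Series({"nGene": 0.05, "cA": 0.05}))
        assert "cA" in c.select_informative(table)


class TestPvalues:
    def test_rank_definition(self):
        m = pd.DataFrame({"p": [0.5, 0.3, 0.2]}, index=list("abc"))
        out = c.affinity_to_pvalues(m)["p"]
        assert out.tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_average_rank_on_ties(self):
        m = pd.DataFrame({"p": [0.9, 0.9, 0.2, 0.1]}, index=list("abcd"))
        out = c.affinity_to_pvalues(m)["p"]
        assert out["a"] == out["b"] == pytest.approx(1.5 / 4)

    def test_zero_affinity_gets_p_one(self):
        m = pd.DataFrame({"p": [0.5, 0.0, 0.2]}, index=list("abc"))
        assert c.affinity_to_pvalues(m)["p"]["b"] == 1.0

    def test_shuffled_affinities_uniform_on_grid(self, rng):
        N = 50
        m = pd.DataFrame({"p": rng.permutation(np.arange(1, N + 1)).astype(float)})
        out = np.sort(c.affinity_to_pvalues(m)["p"].to_numpy())
        np.testing.assert_allclose(out, np.arange(1, N + 1) / N)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            c.affinity_to_pvalues(pd.DataFrame({"p": [1.0, 1.0]}))


class TestCombine:
    def test_direct_methods(self):
        m = pd.DataFrame({"a": [0.4, 0.1], "b": [0.2, 0.3]}, index=["x", "y"])
        assert c.combine(m, "sum").tolist() == pytest.approx([0.6, 0.4])
        assert c.combine(m, "max").tolist() == pytest.approx([0.4, 0.3])
        # harmonic: descending scores weighted 1/i^2
        assert c.combine(m, "harmonic")["x"] == pytest.approx(0.4 + 0.2 / 4)

    def test_fisher_single_study_identity(self):
        pv = pd.DataFrame({"a": [0.5]}, index=["x"])
        m = pd.DataFrame({"a": [0.3]}, index=["x"])
        score = c.combine(m, "fisher", pvalues=pv)
        assert 10 ** (-score["x"]) == pytest.approx(0.5, rel=1e-12)

    def test_fisher_two_studies_closed_form(self):
        # independent oracle: for k=2, combined p = q (1 - ln q), q = p1 p2
        pv = pd.DataFrame({"a": [0.1], "b": [0.1]}, index=["x"])
        m = pd.DataFrame({"a": [0.5], "b": [0.5]}, index=["x"])
        score = c.combine(m, "fisher", pvalues=pv)
        q = 0.01
        assert 10 ** (-score["x"]) == pytest.approx(q * (1 - math.log(q)), rel=1e-10)

    def test_orderstat_single_is_identity(self):
        assert c._orderstat_q(np.array([[0.2]]))[0] == pytest.approx(0.2)

    def test_orderstat_q_matches_brute_force_probability(self, rng):
        # oracle: Q is P(U_(1)<=r1, ..., U_(k)<=rk) estimated by simulation
        r = np.array([[0.2, 0.5, 0.9]])
        q = c._orderstat_q(r)[0]
        draws = np.sort(rng.random((200_000, 3)), axis=1)
        est = np.mean(np.all(draws <= r, axis=1))
        assert q == pytest.approx(est, abs=0.005)

    @pytest.mark.parametrize("method", ["sum", "max", "harmonic", "fisher", "logistic", "orderstat"])
    def test_monotone_in_single_predictor(self, method):
        base = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]}, index=["x", "y"])
        better = base.copy()
        if method in ("sum", "max", "harmonic"):
            better.loc["x", "a"] = 0.9
            worse_scores = c.combine(base, method)
            better_scores = c.combine(better, method)
        else:
            pv = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]}, index=["x", "y"])
            pv_better = pv.copy()
            pv_better.loc["x", "a"] = 0.01
            worse_scores = c.combine(base, method, pvalues=pv)
            better_scores = c.combine(base, method, pvalues=pv_better)
        assert better_scores["x"] >= worse_scores["x"]

    def test_out_of_range_pvalues_rejected(self):
        m = pd.DataFrame({"a": [0.5]}, index=["x"])
        with pytest.raises(ValueError):
            c.combine(m, "fisher", pvalues=pd.DataFrame({"a": [0.0]}, index=["x"]))


class TestNullCalibration:
    """Combining independent uniform p-values must give uniform combined p."""

    @pytest.mark.parametrize("method", ["fisher", "logistic", "orderstat"])
    def test_uniform_null(self, method, rng):
        k, n = 3, 10_000
        pv = pd.DataFrame(rng.random((n, k)), columns=[f"p{i}" for i in range(k)])
        m = pd.DataFrame(rng.random((n, k)), columns=pv.columns)
        scores = c.combine(m, method, pvalues=pv)
        combined_p = 10.0 ** (-scores.to_numpy())
        D = stats.kstest(combined_p, "uniform").statistic
        assert D < 0.02


class TestRate:
    def test_minmax_identity(self):
        out = c.rate(pd.Series({"a": 10.0, "b": 5.0, "c": 0.0}))
        assert out.set_index("gene")["rating"].to_dict() == {"a": 5.0, "b": 2.5, "c": 0.0}

    def test_tie_broken_lexicographically(self):
        out = c.rate(pd.Series({"B": 1.0, "A": 1.0, "C": 0.0}))
        assert out.loc[out["rank"] == 1, "gene"].item() == "A"

    def test_top_slice_count(self, rng):
        scores = pd.Series(rng.random(2000), index=[f"g{i}" for i in range(2000)])
        out = c.rate(scores)
        assert (out["percentile"] <= 5).sum() == 100

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            c.rate(pd.Series({"a": 1.0, "b": 1.0}))
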