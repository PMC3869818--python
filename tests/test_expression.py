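import numpy as np
import pandas as pd
import pytest

from netconverge import (ExpressionStudy, bh_adjust, differential_expression,
                         intersect_signatures, network_overlap,
                         pairwise_comparisons, simulate_expression_study)


def study_from_rows(rows, groups, label="toy"):
    """rows: {gene: [values]}, groups: list of group labels per sample."""
    samples = [f"s{i}" for i in range(len(groups))]
    expr = pd.DataFrame(rows, index=samples).T
    return ExpressionStudy(expression=expr,
                           groups=pd.Series(groups, index=samples), label=label)


def bh_oracle(p, fdr=0.05):
    """Brute-force step-up by the definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= fdr


class TestBhAdjust:
    def test_single_p_is_its_own_q(self):
        q, rej = bh_adjust(np.array([0.01]))
        assert q[0] == pytest.approx(0.01) and rej[0]

    def test_worked_five_value_example(self):
        # frozen from the step-up definition: q_(i) = min_{j>=i} m p_(j)/j
        q, rej = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04, 0.20]))
        assert np.allclose(q, [0.05, 0.05, 0.05, 0.05, 0.20])
        assert rej.sum() == 4

    def test_all_ones_reject_nothing(self):
        q, rej = bh_adjust(np.ones(10))
        assert not rej.any() and np.all(q == 1.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([-0.1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        q, rej = bh_adjust(p)
        q_o, rej_o = bh_oracle(p)
        assert np.allclose(q, q_o, atol=1e-12)
        assert np.array_equal(rej, rej_o)

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=100))
        q, _ = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p - 1e-15)


class TestDifferentialExpression:
    def test_worked_t_example(self):
        # pooled t on (4,5,6) vs (1,2,3): t = 3/sqrt(2/3) = 3.674, df = 4
        study = study_from_rows({"g1": [4, 5, 6, 1, 2, 3]},
                                ["case"] * 3 + ["ctrl"] * 3)
        de = differential_expression(study, "case", "ctrl")
        row = de.iloc[0]
        assert row["log2_fold_change"] == pytest.approx(3.0)
        assert row["t_statistic"] == pytest.approx(3.674, abs=1e-3)
        assert row["p_value"] == pytest.approx(0.0213, abs=5e-4)

    def test_identical_values_give_null_result(self):
        study = study_from_rows({"g1": [2.0] * 6}, ["case"] * 3 + ["ctrl"] * 3)
        de = differential_expression(study, "case", "ctrl")
        assert de["log2_fold_change"].iloc[0] == 0.0
        assert de["p_value"].iloc[0] == 1.0
        assert de["t_statistic"].iloc[0] == 0.0

    def test_label_swap_negates_fold_change_keeps_p(self):
        rng = np.random.default_rng(5)
        study = study_from_rows({f"g{i}": rng.normal(size=8) for i in range(20)},
                                ["a"] * 4 + ["b"] * 4)
        d1 = differential_expression(study, "a", "b")
        d2 = differential_expression(study, "b", "a")
        assert np.allclose(d1["log2_fold_change"], -d2["log2_fold_change"])
        assert np.allclose(d1["p_value"], d2["p_value"])
        assert np.allclose(d1["t_statistic"], -d2["t_statistic"])

    def test_q_at_least_p_and_significance_consistent(self):
        rng = np.random.default_rng(6)
        study = study_from_rows({f"g{i}": rng.normal(size=10) for i in range(50)},
                                ["a"] * 5 + ["b"] * 5)
        de = differential_expression(study, "a", "b", fdr=0.05)
        assert np.all(de["q_value"] >= de["p_value"] - 1e-15)
        assert np.array_equal(de["significant"], de["q_value"] <= 0.05)

    def test_absent_or_tiny_group_rejected(self):
        study = study_from_rows({"g1": [1, 2, 3]}, ["a", "a", "b"])
        with pytest.raises(ValueError, match="absent"):
            differential_expression(study, "c", "a")
        with pytest.raises(ValueError, match="< 2 samples"):
            differential_expression(study, "b", "a")

    def test_detection_power_at_reference_conditions(self):
        # planted log2 effect 2, sigma 1, n = 10/group: the pooled t-test
        # detects the shift (two-sided p < 0.05) in >= 95% of genes
        genes = [f"g{i:04d}" for i in range(2000)]
        study, _ = simulate_expression_study(
            genes, {"ctrl": 10, "case": 10},
            planted={"case": {g: 2.0 for g in genes}}, sigma=1.0,
            rng_seed=99, label="power")
        de = differential_expression(study, "case", "ctrl")
        assert (de["p_value"] < 0.05).mean() >= 0.95


class TestPairwiseComparisons:
    def test_three_groups_give_three_tables(self):
        rng = np.random.default_rng(0)
        study = study_from_rows({f"g{i}": rng.normal(size=9) for i in range(5)},
                                ["HC"] * 3 + ["IFG"] * 3 + ["T2D"] * 3)
        tables = pairwise_comparisons(study)
        assert set(tables) == {"IFG_vs_HC", "T2D_vs_HC", "T2D_vs_IFG"}

    def test_two_groups_give_one_table(self):
        rng = np.random.default_rng(1)
        study = study_from_rows({f"g{i}": rng.normal(size=6) for i in range(5)},
                                ["HC"] * 3 + ["PD"] * 3)
        assert set(pairwise_comparisons(study)) == {"PD_vs_HC"}

    def test_single_group_is_an_error(self):
        study = study_from_rows({"g1": [1, 2, 3]}, ["HC"] * 3)
        with pytest.raises(ValueError, match=">= 2 groups"):
            pairwise_comparisons(study)


def de_table(sig_genes, directions, label):
    """Minimal differential-expression table for intersection tests."""
    genes = sorted(sig_genes)
    return pd.DataFrame({
        "gene": genes,
        "comparison": label,
        "log2_fold_change": [1.0 if directions[g] == "up" else -1.0 for g in genes],
        "t_statistic": 0.0, "p_value": 0.01, "q_value": 0.01,
        "significant": True,
    })


class TestIntersectSignatures:
    def test_intersection_and_concordant_up(self):
        tables = {
            "s1": de_table({"a", "b", "c"}, {"a": "up", "b": "up", "c": "up"}, "s1"),
            "s2": de_table({"b", "c"}, {"b": "up", "c": "down"}, "s2"),
            "s3": de_table({"b", "c", "d"}, {"b": "up", "c": "up", "d": "down"}, "s3"),
        }
        comp = intersect_signatures(tables)
        assert comp.intersection == {"b", "c"}
        assert comp.concordant_up == {"b"}
        assert dict(comp.directions.loc["c"]) == {"s1": "up", "s2": "down", "s3": "up"}

    def test_empty_study_set_empties_intersection(self):
        tables = {"s1": de_table({"a"}, {"a": "up"}, "s1"),
                  "s2": de_table(set(), {}, "s2")}
        comp = intersect_signatures(tables)
        assert comp.intersection == set() and comp.concordant_up == set()

    def test_single_study_is_an_error(self):
        with pytest.raises(ValueError, match="two studies"):
            intersect_signatures({"s1": de_table({"a"}, {"a": "up"}, "s1")})

    def test_planted_concordant_up_recovered_across_three_studies(self):
        genes = [f"g{i:03d}" for i in range(300)]
        up = {"g010", "g020"}
        tables = {}
        for k in range(3):
            planted = {g: 5.0 for g in up} | {genes[100 + 10 * k]: -5.0}
            study, _ = simulate_expression_study(
                genes, {"HC": 10, "CASE": 10}, planted={"CASE": planted},
                sigma=1.0, rng_seed=500 + k, label=f"s{k}")
            tables[f"s{k}"] = differential_expression(study, "CASE", "HC")
        comp = intersect_signatures(tables)
        assert comp.concordant_up == up


class TestNetworkOverlap:
    def test_basic_set_algebra(self):
        assert network_overlap({"app", "x"}, {"app", "y"}) == {"app"}
        assert network_overlap({"a"}, {"b"}) == set()
        assert network_overlap({"a", "b"}, {"a", "b", "c"}) == {"a", "b"}

    def test_accepts_score_table(self):
        table = pd.DataFrame({"gene": ["app", "y"], "score": [0.2, 0.1]})
        assert network_overlap({"app", "x"}, table) == {"app"}


class TestExpressionStudyValidation:
    def test_duplicate_genes_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s2"])
        expr = pd.concat([expr, expr])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionStudy(expression=expr,
                            groups=pd.Series(["a", "b"], index=["s1", "s2"]))

    def test_unlabeled_sample_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="group"):
            ExpressionStudy(expression=expr, groups=pd.Series(["a"], index=["s1"]))

    def test_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(4, 6)),
                            index=[f"g{i}" for i in range(4)],
                            columns=[f"s{i}" for i in range(6)])
        study = ExpressionStudy(expression=expr,
                                groups=pd.Series(["a"] * 3 + ["b"] * 3,
                                                 index=expr.columns))
        study.to_files(tmp_path / "e.tsv", tmp_path / "a.tsv")
        back = ExpressionStudy.from_files(tmp_path / "e.tsv", tmp_path / "a.tsv")
        assert np.allclose(back.expression.to_numpy(), expr.to_numpy())
        assert list(back.groups) == list(study.groups)
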