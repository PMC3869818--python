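import numpy as np
import pandas as pd
import pytest

from netconverge import (adjust_covariates, covariate_screen, delta_delta_ct,
                         group_difference, load_qpcr_table, roc_analysis,
                         simulate_qpcr_cohort)


def qpcr_frame(delta_cts, groups, reference_ct=20.0):
    n = len(delta_cts)
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "group": groups,
        "target_ct": [reference_ct + d for d in delta_cts],
        "reference_ct": [reference_ct] * n,
    })


def auc_oracle(case_scores, control_scores):
    """Brute-force pair counting with ties worth 0.5."""
    total = 0.0
    for c in case_scores:
        for k in control_scores:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(case_scores) * len(control_scores))


class TestDeltaDeltaCt:
    def test_sample_at_calibrator_mean_has_fold_change_one(self):
        data = qpcr_frame([4.0, 4.0, 4.0], ["HC", "HC", "PD"])
        res = delta_delta_ct(data, "HC")
        assert res.per_sample["fold_change"].iloc[2] == pytest.approx(1.0)

    def test_two_cycle_drop_means_fourfold_expression(self):
        data = qpcr_frame([4.0, 4.0, 2.0], ["HC", "HC", "PD"])
        res = delta_delta_ct(data, "HC")
        row = res.per_sample.iloc[2]
        assert row["delta_delta_ct"] == pytest.approx(-2.0)
        assert row["fold_change"] == pytest.approx(4.0)

    def test_one_cycle_gain_halves_expression(self):
        data = qpcr_frame([4.0, 4.0, 5.0], ["HC", "HC", "PD"])
        assert delta_delta_ct(data, "HC").per_sample["fold_change"].iloc[2] \
            == pytest.approx(0.5)

    def test_calibrator_mean_log2_fold_change_is_zero(self):
        rng = np.random.default_rng(0)
        data = qpcr_frame(rng.normal(5, 1, 30),
                          ["HC"] * 15 + ["PD"] * 15)
        res = delta_delta_ct(data, "HC")
        cal = res.per_sample[res.per_sample["group"] == "HC"]
        assert np.log2(cal["fold_change"]).mean() == pytest.approx(0.0, abs=1e-12)
        summary = res.group_summary.set_index("group")
        assert summary.loc["HC", "fold_change_group"] == pytest.approx(1.0)

    def test_missing_reference_ct_drops_sample_with_warning(self, caplog):
        data = qpcr_frame([4.0, 4.0, 2.0], ["HC", "HC", "PD"])
        data.loc[2, "reference_ct"] = np.nan
        import logging
        with caplog.at_level(logging.WARNING):
            res = delta_delta_ct(data, "HC")
        assert len(res.per_sample) == 2
        assert any("missing" in r.message for r in caplog.records)

    def test_empty_calibrator_is_an_error(self):
        data = qpcr_frame([4.0, 2.0], ["PD", "PD"])
        with pytest.raises(ValueError, match="calibrator"):
            delta_delta_ct(data, "HC")

    def test_loader_validates_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tgroup\ttarget_ct\nx\tHC\t20\n")
        with pytest.raises(ValueError, match="reference_ct"):
            load_qpcr_table(path)


class TestGroupDifference:
    def test_worked_t_example_on_delta_ct(self):
        data = qpcr_frame([1, 2, 3, 4, 5, 6],
                          ["PD"] * 3 + ["HC"] * 3)
        t, p = group_difference(data, "PD", "HC")
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_swapping_groups_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        data = qpcr_frame(rng.normal(5, 1, 20), ["PD"] * 10 + ["HC"] * 10)
        t1, p1 = group_difference(data, "PD", "HC")
        t2, p2 = group_difference(data, "HC", "PD")
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_identical_distributions_give_t_zero(self):
        data = qpcr_frame([3.0, 3.0, 3.0, 3.0], ["PD", "PD", "HC", "HC"])
        t, p = group_difference(data, "PD", "HC")
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_small_group_rejected(self):
        data = qpcr_frame([1.0, 2.0, 3.0], ["PD", "HC", "HC"])
        with pytest.raises(ValueError, match="< 2 samples"):
            group_difference(data, "PD", "HC")


class TestCovariateScreen:
    def test_perfectly_linear_covariate(self):
        age = np.arange(50.0, 60.0)
        screen = covariate_screen(2 * age + 1, pd.DataFrame({"age": age}))
        row = screen.iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["p"] < 0.05

    def test_constant_covariate_reported_undefined(self):
        screen = covariate_screen([1.0, 2.0, 3.0, 4.0],
                                  pd.DataFrame({"flat": [7.0] * 4}))
        assert np.isnan(screen["r"].iloc[0])
        assert "constant" in screen["note"].iloc[0]

    def test_binary_covariate_point_biserial(self):
        rng = np.random.default_rng(2)
        sex = pd.Series(rng.choice(["F", "M"], 50))
        vals = np.where(sex == "M", 1.0, 0.0) + rng.normal(0, 0.1, 50)
        screen = covariate_screen(vals, pd.DataFrame({"sex": sex}))
        assert screen["r"].iloc[0] > 0.9

    def test_permuted_covariate_uncorrelated(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=1000)
        cov = rng.permutation(vals)
        screen = covariate_screen(vals, pd.DataFrame({"perm": cov}))
        assert abs(screen["r"].iloc[0]) < 0.1

    def test_too_few_pairs_flagged(self):
        screen = covariate_screen([1.0, 2.0, 3.0],
                                  pd.DataFrame({"x": [1.0, np.nan, np.nan]}))
        assert np.isnan(screen["r"].iloc[0])
        assert "fewer than 3" in screen["note"].iloc[0]


class TestAdjustCovariates:
    def test_no_covariates_equals_difference_of_means(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=20)
        groups = ["HC"] * 10 + ["PD"] * 10
        eff = adjust_covariates(values, groups)
        expected = values[10:].mean() - values[:10].mean()
        assert eff.coefficient == pytest.approx(expected, abs=1e-12)

    def test_all_zero_covariate_is_rank_deficient(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=10)
        groups = ["HC"] * 5 + ["PD"] * 5
        with pytest.raises(ValueError, match="zero"):
            adjust_covariates(values, groups,
                              pd.DataFrame({"zero": np.zeros(10)}))

    def test_planted_confounder_recovered_within_two_se(self):
        data = simulate_qpcr_cohort(n_case=100, n_control=100,
                                    delta_ct_shift=-1.0, sd_ct=1.0,
                                    with_covariates=False,
                                    confounder=("stress", 1.0, 0.8),
                                    rng_seed=11)
        dct = data["target_ct"] - data["reference_ct"]
        raw = adjust_covariates(dct, data["group"], case_group="PD")
        adj = adjust_covariates(dct, data["group"],
                                data[["stress"]], case_group="PD")
        # unadjusted estimate absorbs the confounder path (-1.0 + 0.8)
        assert abs(raw.coefficient - (-0.2)) < 3 * raw.std_error
        assert abs(adj.coefficient - (-1.0)) < 2 * adj.std_error


class TestRocAnalysis:
    def test_perfect_separation(self):
        roc = roc_analysis([3.0, 4.0, 1.0, 2.0], ["PD", "PD", "HC", "HC"],
                           case_label="PD")
        assert roc.auc == 1.0 and roc.ci_high == 1.0

    def test_all_tied_scores_give_half(self):
        roc = roc_analysis([1.0] * 6, ["PD"] * 3 + ["HC"] * 3, case_label="PD")
        assert roc.auc == 0.5

    def test_worked_pair_counting_example(self):
        roc = roc_analysis([3.0, 1.0, 2.0, 0.0], ["PD", "PD", "HC", "HC"],
                           case_label="PD")
        assert roc.auc == pytest.approx(0.75)

    def test_orientation_flip_recorded(self):
        roc = roc_analysis([1.0, 2.0, 3.0, 4.0], ["PD", "PD", "HC", "HC"],
                           case_label="PD")
        assert roc.flipped and roc.auc >= 0.5

    def test_ci_contains_auc_and_is_clipped(self):
        rng = np.random.default_rng(6)
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        roc = roc_analysis(scores, ["PD"] * 30 + ["HC"] * 30, case_label="PD")
        assert 0.0 <= roc.ci_low <= roc.auc <= roc.ci_high <= 1.0

    def test_one_class_empty_is_an_error(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["PD", "PD"], case_label="PD")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(700 + seed)
        n1, n0 = rng.integers(2, 15, size=2)
        # integer scores force ties, exercising the 0.5 convention
        case = rng.integers(0, 6, n1).astype(float)
        ctrl = rng.integers(0, 6, n0).astype(float)
        expected = auc_oracle(case, ctrl)
        if np.mean(case) < np.mean(ctrl):
            expected = 1.0 - expected  # orientation flip
        roc = roc_analysis(np.r_[case, ctrl], ["PD"] * n1 + ["HC"] * n0,
                           case_label="PD")
        assert roc.auc == pytest.approx(expected, abs=1e-12)
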