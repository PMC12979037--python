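import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tracescore.differential import (
    compare_models,
    concordance,
    paired_metabolite_test,
)

from .conftest import make_scores
from .oracles import anova_f_oracle

A3 = {"a1": None, "a2": None, "a3": None}


def scores_two_groups(a_values, b_values, met="X", ref=True):
    values = {
        met: {
            **{f"a{i+1}": v for i, v in enumerate(a_values)},
            **{f"b{i+1}": v for i, v in enumerate(b_values)},
        }
    }
    if ref:
        n_a, n_b = len(a_values), len(b_values)
        values["glutamate"] = {
            **{f"a{i+1}": 1.0 for i in range(n_a)},
            **{f"b{i+1}": 1.0 for i in range(n_b)},
        }
    return make_scores(values)


GROUP_A = ["a1", "a2", "a3"]
GROUP_B = ["b1", "b2", "b3"]


class TestCompareModels:
    def test_pooled_t_matches_hand_computation(self):
        # means 1.0 vs 2.0, pooled s^2 = 0.01 -> t = 1/sqrt(0.01*2/3) = 12.247
        scores = scores_two_groups([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        rec = compare_models(scores, GROUP_A, GROUP_B, test="pooled").set_index(
            "metabolite_id"
        ).loc["X"]
        assert rec["fold_change"] == pytest.approx(2.0)
        assert rec["t_statistic"] == pytest.approx(np.sqrt(150.0), rel=1e-12)
        assert rec["p_value"] == pytest.approx(
            2 * stats.t.sf(np.sqrt(150.0), df=4), rel=1e-12
        )
        assert rec["significant"]

    def test_identical_groups_are_null(self):
        scores = scores_two_groups([1.0, 1.2, 0.8], [1.0, 1.2, 0.8])
        rec = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id").loc["X"]
        assert rec["fold_change"] == pytest.approx(1.0)
        assert rec["t_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert rec["p_value"] == pytest.approx(1.0)
        assert not rec["significant"]

    def test_zero_variance_identical_triplets(self):
        scores = scores_two_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        rec = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id").loc["X"]
        assert rec["t_statistic"] == 0.0 and rec["p_value"] == 1.0

    def test_fold_change_gate_blocks_small_effects(self):
        # highly significant but only 1.2-fold
        scores = scores_two_groups([1.0, 1.001, 0.999], [1.2, 1.201, 1.199])
        rec = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id").loc["X"]
        assert rec["p_value"] < 0.001 and not rec["significant"]

    def test_exclusive_status_when_one_group_unscored(self):
        scores = scores_two_groups([1.0, 1.1, 0.9], [None, None, None])
        rec = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id").loc["X"]
        assert rec["status"] == "exclusive_to_A"
        assert np.isnan(rec["p_value"]) and rec["significant"]
        scores = scores_two_groups([1.0, 1.1, 0.9], [2.0, None, None])
        rec = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id").loc["X"]
        assert rec["status"] == "exclusive_to_A"

    def test_swap_symmetry_inverts_fold_change(self):
        rng = np.random.default_rng(5)
        values = {
            f"m{k}": {
                **{f"a{i+1}": float(v) for i, v in enumerate(rng.lognormal(0, 0.3, 3))},
                **{f"b{i+1}": float(v) for i, v in enumerate(rng.lognormal(0.2, 0.3, 3))},
            }
            for k in range(8)
        }
        scores = make_scores(values)
        ab = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id")
        ba = compare_models(scores, GROUP_B, GROUP_A).set_index("metabolite_id")
        product = (ab["fold_change"] * ba["fold_change"]).dropna()
        np.testing.assert_allclose(product, 1.0, atol=1e-12)
        np.testing.assert_allclose(
            ab["p_value"].sort_index(), ba["p_value"].sort_index(), atol=1e-12
        )

    def test_overlapping_or_tiny_groups_error(self):
        scores = scores_two_groups([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        with pytest.raises(ValueError, match="overlap"):
            compare_models(scores, GROUP_A, GROUP_A)
        with pytest.raises(ValueError, match=">= 2"):
            compare_models(scores, ["a1"], GROUP_B)

    def test_sorted_by_p_value(self):
        rng = np.random.default_rng(3)
        values = {}
        for k, shift in enumerate([0.0, 0.5, 2.0]):
            a = rng.normal(1, 0.05, 3)
            b = rng.normal(1 + shift, 0.05, 3)
            values[f"m{k}"] = {
                **{f"a{i+1}": float(v) for i, v in enumerate(a)},
                **{f"b{i+1}": float(v) for i, v in enumerate(b)},
            }
        result = compare_models(make_scores(values), GROUP_A, GROUP_B)
        tested_p = result.loc[result["status"] == "tested", "p_value"]
        assert list(tested_p) == sorted(tested_p)


class TestConcordance:
    def test_identity_and_sign_symmetry(self):
        x = pd.Series({"m1": 0.1, "m2": 0.4, "m3": 0.7, "m4": 0.2})
        res = concordance(x, x)
        assert res.r == pytest.approx(1.0) and res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        res = concordance(x, -x)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    def test_matches_textbook_closed_form(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([1.1, 1.9, 3.2, 3.8], index=list("abcd"))
        res = concordance(x, y)
        assert res.slope == pytest.approx(0.94, abs=1e-12)
        assert res.intercept == pytest.approx(0.15, abs=1e-12)
        assert res.r == pytest.approx(18.8 / np.sqrt(360.0), abs=1e-12)
        assert res.n_points == 4

    def test_inner_join_and_degenerate_errors(self):
        x = pd.Series({"m1": 1.0, "m2": 2.0, "m3": 3.0})
        with pytest.raises(ValueError, match=">= 3"):
            concordance(x, pd.Series({"m1": 1.0, "m2": 2.0}))
        flat = pd.Series({"m1": 1.0, "m2": 1.0, "m3": 1.0})
        with pytest.raises(ValueError, match="variance"):
            concordance(flat, x)


class TestPairedMetaboliteTest:
    def test_identical_groups_null(self):
        scores = make_scores(
            {"X": {s: v for s, v in zip(
                ["a1", "a2", "a3", "b1", "b2", "b3", "c1", "c2", "c3"],
                [1.0, 2.0, 3.0] * 3)}}
        )
        groups = {"g1": GROUP_A, "g2": GROUP_B, "g3": ["c1", "c2", "c3"]}
        res = paired_metabolite_test(scores, "X", groups)
        assert res.design == "one_way_anova"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_anova_matches_decomposition_oracle(self):
        arrays = [
            np.array([0.0, 0.01, -0.01]),
            np.array([0.0, 0.02, -0.02]),
            np.array([10.0, 10.1, 9.9]),
        ]
        scores = make_scores(
            {"X": {s: float(v) for s, v in zip(
                ["a1", "a2", "a3", "b1", "b2", "b3", "c1", "c2", "c3"],
                np.concatenate(arrays))}}
        )
        groups = {"g1": GROUP_A, "g2": GROUP_B, "g3": ["c1", "c2", "c3"]}
        res = paired_metabolite_test(scores, "X", groups)
        assert res.statistic == pytest.approx(anova_f_oracle(arrays), rel=1e-10)
        assert res.p_value < 0.001

    def test_two_groups_route_to_t_test_consistent_with_compare_models(self):
        scores = scores_two_groups([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        res = paired_metabolite_test(scores, "X", {"A": GROUP_A, "B": GROUP_B})
        volcano = compare_models(scores, GROUP_A, GROUP_B).set_index("metabolite_id")
        assert res.design == "t_test"
        assert res.p_value == pytest.approx(volcano.loc["X", "p_value"], rel=1e-12)

    def test_small_group_errors(self):
        scores = scores_two_groups([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        with pytest.raises(ValueError, match=">= 2"):
            paired_metabolite_test(scores, "X", {"A": ["a1"], "B": GROUP_B})
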