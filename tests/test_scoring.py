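import numpy as np
import pandas as pd
import pytest

import tracescore as ts
from tracescore.correction import CorrectedDistribution
from tracescore.scoring import (
    FilterPolicy,
    compute_labeling_scores,
    isotopologue_report,
    steady_state_ratio,
)


def dist(met, sample, fractions, pool=100.0):
    f = None if fractions is None else np.asarray(fractions, dtype=float)
    return CorrectedDistribution(met, sample, f, pool, 0.0, undetected=f is None)


@pytest.fixture()
def basic_corrected():
    return [
        dist("glutamate", "s1", [0.6, 0.4], pool=1000.0),
        dist("X", "s1", [0.8, 0.2], pool=500.0),
        dist("unlabeled_met", "s1", [1.0, 0.0], pool=400.0),
        dist("ghost", "s1", None, pool=0.0),
    ]


class TestLabelingScores:
    def test_score_is_ratio_to_reference(self, basic_corrected):
        table = compute_labeling_scores(basic_corrected).set_index("metabolite_id")
        assert table.loc["X", "score"] == pytest.approx(0.2 / 0.4)

    def test_reference_self_score_exactly_one(self, basic_corrected):
        table = compute_labeling_scores(basic_corrected).set_index("metabolite_id")
        assert table.loc["glutamate", "score"] == 1.0

    def test_zero_labeling_filtered_without_score(self, basic_corrected):
        table = compute_labeling_scores(basic_corrected).set_index("metabolite_id")
        row = table.loc["unlabeled_met"]
        assert not row["passed_filters"] and np.isnan(row["score"])

    def test_completeness_no_silent_drops(self, basic_corrected):
        table = compute_labeling_scores(basic_corrected)
        assert len(table) == len(basic_corrected)
        assert not table.loc[
            table["metabolite_id"] == "ghost", "passed_filters"
        ].item()

    def test_pool_filter_fraction_of_sample_median(self):
        corrected = [
            dist("glutamate", "s1", [0.6, 0.4], pool=1000.0),
            dist("big", "s1", [0.5, 0.5], pool=900.0),
            dist("trace_pool", "s1", [0.5, 0.5], pool=5.0),
        ]
        policy = FilterPolicy(min_pool_size=0.01)  # 1% of median = 9.0
        table = compute_labeling_scores(corrected, policy).set_index("metabolite_id")
        assert table.loc["big", "passed_filters"].item()
        assert not table.loc["trace_pool", "passed_filters"].item()
        absolute = FilterPolicy(min_pool_size=2.0, pool_size_mode="absolute")
        table = compute_labeling_scores(corrected, absolute).set_index("metabolite_id")
        assert table.loc["trace_pool", "passed_filters"].item()

    def test_missing_or_unlabeled_reference_errors(self):
        with pytest.raises(ValueError, match="missing or undetected"):
            compute_labeling_scores([dist("X", "s1", [0.8, 0.2])])
        with pytest.raises(ValueError, match="zero"):
            compute_labeling_scores(
                [
                    dist("glutamate", "s1", [1.0, 0.0]),
                    dist("X", "s1", [0.8, 0.2]),
                ]
            )

    def test_tracer_free_samples_routed_out_of_scoring(self, basic_corrected):
        corrected = basic_corrected + [dist("glutamate", "blank", [1.0, 0.0])]
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "blank"],
                "tracer_condition": ["traced", "unlabeled"],
                "model_system": ["A", "A"],
            }
        )
        table = compute_labeling_scores(basic_corrected + corrected[-1:], samples=samples)
        assert "blank" not in set(table["sample_id"])

    def test_monotone_in_total_labeling(self):
        scores = []
        for tl in (0.1, 0.2, 0.3, 0.39):
            table = compute_labeling_scores(
                [
                    dist("glutamate", "s1", [0.6, 0.4]),
                    dist("X", "s1", [1 - tl, tl]),
                ]
            ).set_index("metabolite_id")
            scores.append(table.loc["X", "score"])
        assert np.all(np.diff(scores) > 0)

    def test_group_mean_normalization_option(self):
        corrected = [
            dist("glutamate", "s1", [0.7, 0.3]),
            dist("glutamate", "s2", [0.5, 0.5]),
            dist("X", "s1", [0.8, 0.2]),
            dist("X", "s2", [0.8, 0.2]),
        ]
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "tracer_condition": ["traced", "traced"],
                "model_system": ["A", "A"],
            }
        )
        table = compute_labeling_scores(
            corrected, samples=samples, normalization="group-mean"
        ).set_index(["metabolite_id", "sample_id"])
        assert table.loc[("X", "s1"), "score"] == pytest.approx(0.2 / 0.4)
        assert table.loc[("X", "s2"), "score"] == pytest.approx(0.2 / 0.4)


class TestScaleInvariance:
    def test_scores_invariant_to_per_sample_intensity_rescaling(self, sxo_sim):
        base = ts.IsotopeTracingModel(
            sxo_sim.dataset, correction_mode="all-elements"
        ).fit()
        intensities, mets, samples = sxo_sim.dataset.to_frames()
        factors = {sid: 3.7 + 0.1 * k for k, sid in enumerate(samples["sample_id"])}
        intensities["intensity"] *= intensities["sample_id"].map(factors)
        rescaled_ds = ts.TracingDataset.from_frames(intensities, mets, samples)
        rescaled = ts.IsotopeTracingModel(
            rescaled_ds, correction_mode="all-elements"
        ).fit()
        left = base.scores.set_index(["metabolite_id", "sample_id"]).sort_index()
        right = rescaled.scores.set_index(["metabolite_id", "sample_id"]).sort_index()
        assert (left["passed_filters"] == right["passed_filters"]).all()
        drift = (left["score"] - right["score"]).abs().max()
        assert drift <= 1e-12


class TestSteadyStateRatio:
    def test_examples(self):
        pools = {"dihydrouracil": 50.0, "uracil": 100.0}
        assert steady_state_ratio(pools, "dihydrouracil", "uracil") == 0.5
        assert steady_state_ratio({"a": 7.0, "b": 7.0}, "a", "b") == 1.0

    def test_zero_denominator_errors_zero_numerator_warns(self, caplog):
        with pytest.raises(ValueError, match="zero"):
            steady_state_ratio({"a": 1.0, "b": 0.0}, "a", "b")
        with caplog.at_level("WARNING", logger="tracescore.scoring"):
            assert steady_state_ratio({"a": 0.0, "b": 2.0}, "a", "b") == 0.0
        assert any("undetected" in r.message for r in caplog.records)

    def test_missing_metabolite_errors(self):
        with pytest.raises(KeyError):
            steady_state_ratio({"a": 1.0}, "a", "b")


class TestIsotopologueReport:
    def test_traced_glutamine_m2_matches_simulated_enrichment(self, sxo_sim, sxo_results):
        report = isotopologue_report(
            sxo_results.corrected, "glutamine", 2, samples=sxo_results.samples
        )
        traced = report[report["tracer_condition"] == "traced"]
        blank = report[report["tracer_condition"] == "unlabeled"]
        truth = sxo_sim.truth.query(
            "metabolite_id == 'glutamine' and isotopologue == 2"
        )["true_fraction"].iloc[0]
        assert traced["fractional_enrichment"].mean() == pytest.approx(truth, abs=0.03)
        assert blank["fractional_enrichment"].max() < 0.01

    def test_unknown_metabolite_errors(self, sxo_results):
        with pytest.raises(KeyError):
            isotopologue_report(sxo_results.corrected, "nonesuch", 0)
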