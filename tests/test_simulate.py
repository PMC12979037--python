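from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import tracescore as ts
from tracescore.correction import total_labeling
from tracescore.io import MoleculeSpec, parse_formula
from tracescore.simulate import (
    GroupSpec,
    NetworkMetabolite,
    NetworkSpec,
    ScenarioConfig,
    SourceDraw,
    TracerEntry,
    TransferRule,
    isotopologue_distribution,
    propagate_labels,
)

from .oracles import enumeration_label_distribution


def met(mid, formula, n, pool=1e5):
    return NetworkMetabolite(MoleculeSpec(mid, parse_formula(formula), n), pool)


def two_step_network(enrichment=0.5, mode="joint", fraction_new=0.6):
    """Glutamine -> product taking one nitrogen from the amide position."""
    return NetworkSpec(
        metabolites=(
            met("glutamine", "C5H10N2O3", 2, 1e6),
            met("glutamate", "C5H9NO4", 1, 1e6),
            met("product", "C4H7NO4", 1, 1e5),
        ),
        rules=(
            TransferRule(
                "glutamate", (SourceDraw("glutamine", {0: 0}),), 0.9, None
            ),
            TransferRule(
                "product", (SourceDraw("glutamine", {0: 1}),), fraction_new, "path"
            ),
        ),
        tracer=TracerEntry("glutamine", enrichment, mode),
    )


class TestPropagation:
    def test_independent_mode_is_binomial(self):
        net = two_step_network(enrichment=0.5, mode="independent")
        dist = isotopologue_distribution(propagate_labels(net)["glutamine"])
        np.testing.assert_allclose(dist, [0.25, 0.5, 0.25], atol=1e-12)

    def test_joint_mode_is_pure_m2(self):
        net = two_step_network(enrichment=0.7, mode="joint")
        dist = isotopologue_distribution(propagate_labels(net)["glutamine"])
        np.testing.assert_allclose(dist, [0.3, 0.0, 0.7], atol=1e-12)

    def test_fraction_new_mixing(self):
        # one amide nitrogen at enrichment 0.5, fraction-new 0.6 -> TL 0.3
        net = two_step_network(enrichment=0.5, mode="joint", fraction_new=0.6)
        dist = isotopologue_distribution(propagate_labels(net)["product"])
        assert 1.0 - dist[0] == pytest.approx(0.3, abs=1e-12)

    def test_activity_multiplier_zero_kills_pathway_labeling(self):
        net = two_step_network()
        joints = propagate_labels(net, activity={"path": 0.0})
        dist = isotopologue_distribution(joints["product"])
        assert dist[0] == 1.0

    def test_distributions_on_simplex(self):
        network, _ = ts.preset_scenario("sxo_vs_gsc")
        for joint in propagate_labels(network).values():
            assert np.all(joint >= 0)
            np.testing.assert_allclose(joint.sum(), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "activity", [{}, {"purine_degradation": 0.3, "pyrimidine_degradation": 0.0}]
    )
    def test_matches_enumeration_oracle(self, activity):
        network, _ = ts.preset_scenario("sxo_vs_gsc")
        joints = propagate_labels(network, activity)
        oracle = enumeration_label_distribution(network, activity)
        for mid, joint in joints.items():
            expected = np.zeros_like(joint)
            for state, prob in oracle[mid].items():
                expected[state] = prob
            np.testing.assert_allclose(joint, expected, atol=1e-12)

    def test_cyclic_network_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            NetworkSpec(
                metabolites=(
                    met("glutamine", "C5H10N2O3", 2),
                    met("a", "C1N1H1", 1),
                    met("b", "C1N1H1", 1),
                ),
                rules=(
                    TransferRule("a", (SourceDraw("b", {0: 0}),), 0.5, None),
                    TransferRule("b", (SourceDraw("a", {0: 0}),), 0.5, None),
                ),
                tracer=TracerEntry("glutamine", 0.5),
            )

    def test_bad_enrichment_rejected(self):
        with pytest.raises(ValueError, match="enrichment"):
            TracerEntry("glutamine", 1.5)


class TestSimulateDataset:
    def test_noise_free_fidelity(self):
        network, scenario = ts.preset_scenario("sxo_vs_gsc")
        scenario = replace(scenario, noise_cv=0.0)
        sim = ts.simulate_dataset(network, scenario, seed=0)
        res = ts.IsotopeTracingModel(sim.dataset, correction_mode="all-elements").fit()
        truth = sim.truth.drop_duplicates(["group", "metabolite_id"]).set_index(
            ["group", "metabolite_id"]
        )
        for dist in res.corrected:
            meta = sim.dataset.samples[dist.sample_id]
            if meta.tracer_condition != "traced" or dist.undetected:
                continue
            expected = truth.loc[(meta.model_system, dist.metabolite_id)][
                "true_total_labeling"
            ]
            assert total_labeling(dist) == pytest.approx(float(expected), abs=1e-6)

    def test_zero_enrichment_means_zero_labeling_everywhere(self):
        network, scenario = ts.preset_scenario("sxo_vs_gsc")
        network = replace(network, tracer=TracerEntry("glutamine", 0.0, "joint"))
        scenario = replace(scenario, noise_cv=0.0)
        sim = ts.simulate_dataset(network, scenario, seed=0)
        assert (sim.truth["true_total_labeling"] == 0.0).all()
        corrected = ts.correct_dataset(sim.dataset, mode="all-elements")
        tls = [total_labeling(d) for d in corrected if not d.undetected]
        assert max(tls) < 1e-6

    def test_seed_determinism(self):
        network, scenario = ts.preset_scenario("sxo_vs_gsc")
        one = ts.simulate_dataset(network, scenario, seed=5)
        two = ts.simulate_dataset(network, scenario, seed=5)
        pd.testing.assert_frame_equal(
            one.dataset.to_frames()[0], two.dataset.to_frames()[0]
        )
        pd.testing.assert_frame_equal(one.truth, two.truth)

    def test_undetectable_metabolite_emitted_as_zero(self, sxo_sim):
        gsc_samples = [
            s.sample_id
            for s in sxo_sim.dataset.samples.values()
            if s.model_system == "GSC_like"
        ]
        for sid in gsc_samples:
            assert sxo_sim.dataset.vector("GDP-mannose", sid).undetected

    def test_truth_marks_expected_differential_directions(self, sxo_sim):
        truth = sxo_sim.truth.drop_duplicates(["group", "metabolite_id"])
        wide = truth.pivot(
            index="metabolite_id", columns="group", values="true_total_labeling"
        )
        for purine in ("adenosine", "hypoxanthine"):
            assert wide.loc[purine, "GSC_like"] > wide.loc[purine, "SXO_like"]
        flags = truth.drop_duplicates("metabolite_id").set_index("metabolite_id")[
            "differential"
        ]
        assert flags["adenosine"] and flags["uracil"] and flags["GDP-mannose"]
        assert not flags["glutamate"] and not flags["AMP"]


class TestPresets:
    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="sxo_vs_gsc"):
            ts.preset_scenario("bogus")

    def test_null_preset_has_no_differential_truth(self):
        network, scenario = ts.preset_scenario("null")
        sim = ts.simulate_dataset(network, scenario, seed=1)
        assert not sim.truth["differential"].any()

    def test_concordance_preset_r2_near_one_at_low_noise(self):
        network, scenario = ts.preset_scenario("preconditioning_concordance")
        sim = ts.simulate_dataset(network, replace(scenario, noise_cv=0.05), seed=2)
        res = ts.IsotopeTracingModel(sim.dataset, correction_mode="all-elements").fit()
        assert res.concordance("precond_24h", "precond_120h").r_squared > 0.9

    def test_preset_sets_reference_network_metabolites(self):
        network, _ = ts.preset_scenario("sxo_vs_gsc")
        ids = {m.spec.metabolite_id for m in network.metabolites}
        sets = ts.preset_metabolite_sets()
        assert len(sets) >= 16
        for s in sets:
            assert set(s.member_ids) <= ids
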