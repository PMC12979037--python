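import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tracescore as ts

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("tracescore").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sxo_sim() -> ts.SimulationResult:
    """One simulated explant-vs-cell-line dataset (n=3/group, CV 0.10)."""
    network, scenario = ts.preset_scenario("sxo_vs_gsc")
    return ts.simulate_dataset(network, scenario, seed=11)


@pytest.fixture(scope="session")
def sxo_results(sxo_sim) -> ts.IsotopeTracingResults:
    model = ts.IsotopeTracingModel(sxo_sim.dataset, correction_mode="all-elements")
    return model.fit()


@pytest.fixture()
def tiny_frames():
    """Minimal 1-metabolite (glutamine, n=2), 2-sample three-table input."""
    intensities = pd.DataFrame(
        {
            "metabolite_id": ["glutamine"] * 6,
            "sample_id": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "isotopologue": [0, 1, 2, 0, 1, 2],
            "intensity": [800.0, 50.0, 150.0, 900.0, 40.0, 60.0],
        }
    )
    metabolites = pd.DataFrame(
        {
            "metabolite_id": ["glutamine"],
            "formula": ["C5H10N2O3"],
            "tracer_atom_count": [2],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "model_system": ["A", "A"],
            "tracer_condition": ["traced", "traced"],
            "precondition_hours": [120.0, 120.0],
            "replicate": [1, 2],
        }
    )
    return intensities, metabolites, samples


def make_scores(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a labeling-score table from {metabolite: {sample: score}}."""
    rows = []
    for met, by_sample in values.items():
        for sid, score in by_sample.items():
            rows.append(
                {
                    "metabolite_id": met,
                    "sample_id": sid,
                    "total_labeling": np.nan if score is None else score,
                    "pool_size": 1.0,
                    "passed_filters": score is not None,
                    "score": np.nan if score is None else score,
                }
            )
    return pd.DataFrame(rows)
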