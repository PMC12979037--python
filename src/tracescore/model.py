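"""Model/Results facade over the tracing pipeline.

:class:`IsotopeTracingModel` is built from a validated dataset and holds the
analysis configuration (correction mode, quality filters, reference
metabolite); ``fit()`` performs natural-abundance correction and scoring and
returns an :class:`IsotopeTracingResults` carrying the corrected
distributions, the labeling-score table and QC diagnostics. Group
comparisons, concordance and set enrichment hang off the results object.
"""

from __future__ import annotations

from typing import Collection, Sequence

import numpy as np
import pandas as pd

from .correction import (
    AbundanceTable,
    CorrectedDistribution,
    correct_dataset,
    corrected_frame,
    total_labeling,
)
from .differential import ConcordanceResult, compare_models, concordance
from .enrichment import run_qea
from .io import MetaboliteSet, TracingDataset, read_tracing_dataset
from .scoring import FilterPolicy, compute_labeling_scores, isotopologue_report

__all__ = ["IsotopeTracingModel", "IsotopeTracingResults"]


class IsotopeTracingModel:
    """Stable-isotope tracing analysis of one dataset.

    Parameters
    ----------
    dataset
        A validated :class:`~tracescore.io.TracingDataset`.
    correction_mode
        ``"tracer-only"`` (default; high-resolution instruments) or
        ``"all-elements"`` (unit resolution, and simulated data — the
        simulator contaminates spectra with all-element natural abundance).
    filter_policy, reference_metabolite
        Scoring configuration; see :class:`~tracescore.scoring.FilterPolicy`.
    """

    def __init__(
        self,
        dataset: TracingDataset,
        correction_mode: str = "tracer-only",
        abundances: AbundanceTable | None = None,
        filter_policy: FilterPolicy | None = None,
        reference_metabolite: str = "glutamate",
    ) -> None:
        self.dataset = dataset
        self.correction_mode = correction_mode
        self.abundances = abundances
        self.filter_policy = filter_policy or FilterPolicy()
        self.reference_metabolite = reference_metabolite

    @classmethod
    def from_tables(
        cls,
        intensity_path,
        annotation_path,
        metadata_path,
        **kwargs,
    ) -> "IsotopeTracingModel":
        """Build a model directly from the three on-disk tables."""
        dataset = read_tracing_dataset(intensity_path, annotation_path, metadata_path)
        return cls(dataset, **kwargs)

    def fit(self) -> "IsotopeTracingResults":
        """Correct, score and QC the dataset."""
        corrected = correct_dataset(
            self.dataset, mode=self.correction_mode, abundances=self.abundances
        )
        samples = self.dataset.samples_frame()
        scores = compute_labeling_scores(
            corrected,
            policy=self.filter_policy,
            reference_metabolite=self.reference_metabolite,
            samples=samples,
        )
        return IsotopeTracingResults(self, corrected, scores, samples)


class IsotopeTracingResults:
    """Fitted tracing results: corrected fractions, scores and diagnostics."""

    def __init__(
        self,
        model: IsotopeTracingModel,
        corrected: list[CorrectedDistribution],
        scores: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> None:
        self.model = model
        self.corrected = corrected
        self.scores = scores
        self.samples = samples

    @property
    def corrected_frame(self) -> pd.DataFrame:
        return corrected_frame(self.corrected)

    def samples_of(self, model_system: str, traced_only: bool = True) -> list[str]:
        """Sample ids belonging to one model system."""
        frame = self.samples
        mask = frame["model_system"] == model_system
        if traced_only:
            mask &= frame["tracer_condition"] == "traced"
        ids = list(frame.loc[mask, "sample_id"])
        if not ids:
            raise KeyError(f"no samples for model system {model_system!r}")
        return ids

    def compare_groups(
        self, group_a: str | Collection[str], group_b: str | Collection[str], **kwargs
    ) -> pd.DataFrame:
        """Volcano comparison between two model systems (or sample-id sets)."""
        return compare_models(
            self.scores,
            self._resolve(group_a),
            self._resolve(group_b),
            **kwargs,
        )

    def set_enrichment(
        self,
        sets: Sequence[MetaboliteSet],
        group_a: str | Collection[str],
        group_b: str | Collection[str],
        n_permutations: int = 9999,
        seed: int = 0,
        **kwargs,
    ) -> pd.DataFrame:
        """Permutation QEA between two model systems."""
        return run_qea(
            self.scores,
            sets,
            self._resolve(group_a),
            self._resolve(group_b),
            n_permutations=n_permutations,
            seed=seed,
            **kwargs,
        )

    def concordance(
        self,
        group_a: str | Collection[str],
        group_b: str | Collection[str],
        on: str = "total_labeling",
    ) -> ConcordanceResult:
        """Per-metabolite labeling concordance between two conditions.

        Compares the per-metabolite mean of ``on`` (``total_labeling`` by
        default, or ``score``) across the two groups' traced replicates.
        """
        if on not in ("total_labeling", "score"):
            raise ValueError("on must be 'total_labeling' or 'score'")
        x = self._group_means(self._resolve(group_a), on)
        y = self._group_means(self._resolve(group_b), on)
        return concordance(x, y)

    def isotopologue_report(self, metabolite_id: str, i: int) -> pd.DataFrame:
        return isotopologue_report(
            self.corrected, metabolite_id, i, samples=self.samples
        )

    def qc(
        self,
        reference_floor: float = 0.05,
        background_ceiling: float = 0.01,
    ) -> pd.DataFrame:
        """Per-sample QC: reference labeling and tracer-free background.

        Flags traced samples whose reference-metabolite total labeling falls
        below ``reference_floor`` (tracer never arrived) and unlabeled
        samples whose median total labeling exceeds ``background_ceiling``
        (label contamination or mis-annotation).
        """
        reference = self.model.reference_metabolite
        by_sample: dict[str, list[float]] = {}
        ref_tl: dict[str, float] = {}
        for dist in self.corrected:
            if dist.undetected:
                continue
            tl = total_labeling(dist)
            by_sample.setdefault(dist.sample_id, []).append(tl)
            if dist.metabolite_id == reference:
                ref_tl[dist.sample_id] = tl
        rows = []
        for sample in self.samples.itertuples(index=False):
            sid = sample.sample_id
            ref = ref_tl.get(sid, np.nan)
            med = float(np.median(by_sample.get(sid, [np.nan])))
            flags = []
            if sample.tracer_condition == "traced" and not (ref >= reference_floor):
                flags.append("low_reference_labeling")
            if sample.tracer_condition == "unlabeled" and med > background_ceiling:
                flags.append("tracer_free_background_high")
            rows.append(
                {
                    "sample_id": sid,
                    "model_system": sample.model_system,
                    "tracer_condition": sample.tracer_condition,
                    "reference_total_labeling": ref,
                    "median_total_labeling": med,
                    "flags": ";".join(flags),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary."""
        n_mets = len({d.metabolite_id for d in self.corrected})
        n_samples = len(self.samples)
        n_traced = int((self.samples["tracer_condition"] == "traced").sum())
        passed = int(self.scores["passed_filters"].sum())
        total_rows = len(self.scores)
        qc = self.qc()
        flagged = qc.loc[qc["flags"] != "", "sample_id"].tolist()
        lines = [
            "Isotope tracing results",
            "=" * 46,
            f"metabolites:            {n_mets}",
            f"samples:                {n_samples} ({n_traced} traced)",
            f"correction mode:        {self.model.correction_mode}",
            f"reference metabolite:   {self.model.reference_metabolite}",
            f"scored rows:            {passed}/{total_rows} passed filters",
            f"QC-flagged samples:     {flagged if flagged else 'none'}",
        ]
        ref_rows = qc.loc[qc["tracer_condition"] == "traced"]
        if len(ref_rows):
            lines.append(
                "reference labeling:     "
                f"mean {ref_rows['reference_total_labeling'].mean():.3f} "
                f"(range {ref_rows['reference_total_labeling'].min():.3f}-"
                f"{ref_rows['reference_total_labeling'].max():.3f})"
            )
        return "\n".join(lines)

    # -- helpers -----------------------------------------------------------

    def _resolve(self, group: str | Collection[str]) -> list[str]:
        if isinstance(group, str):
            return self.samples_of(group)
        return list(group)

    def _group_means(self, sample_ids: Collection[str], on: str) -> pd.Series:
        frame = self.scores.loc[
            self.scores["sample_id"].isin(set(sample_ids))
            & self.scores["passed_filters"]
        ]
        return frame.groupby("metabolite_id")[on].mean()
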