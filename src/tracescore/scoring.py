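"""Metabolite Labeling Score and steady-state pool metrics.

The Metabolite Labeling Score makes label accumulation comparable across
model systems that differ in proliferation, de novo precursor synthesis and
intercellular cycling: each metabolite's total labeling (1 − corrected M+0
fraction) is divided by label accumulation in a reference metabolite
(glutamate for a glutamine tracer) measured in the same sample. Metabolites
are first filtered for total labeling > 0 and an adequate total pool size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .correction import CorrectedDistribution, fractional_enrichment, total_labeling

logger = logging.getLogger(__name__)

__all__ = [
    "FilterPolicy",
    "compute_labeling_scores",
    "steady_state_ratio",
    "isotopologue_report",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Quality filters applied before scoring.

    ``min_total_labeling`` is a strict lower bound (default 0: any labeling).
    Pool adequacy is either an absolute intensity floor or, by default, a
    fraction of the sample's median detected-metabolite pool (default 1%),
    which is scale-free across instruments.
    """

    min_total_labeling: float = 0.0
    min_pool_size: float = 0.01
    pool_size_mode: str = "fraction-of-sample-median"

    def __post_init__(self) -> None:
        if self.min_total_labeling < 0:
            raise ValueError("min_total_labeling must be >= 0")
        if self.min_pool_size < 0:
            raise ValueError("min_pool_size must be >= 0")
        if self.pool_size_mode not in ("absolute", "fraction-of-sample-median"):
            raise ValueError(
                "pool_size_mode must be 'absolute' or 'fraction-of-sample-median'"
            )

    def resolve_threshold(self, sample_median_pool: float) -> float:
        if self.pool_size_mode == "absolute":
            return self.min_pool_size
        return self.min_pool_size * sample_median_pool


def compute_labeling_scores(
    corrected: Iterable[CorrectedDistribution],
    policy: FilterPolicy | None = None,
    reference_metabolite: str = "glutamate",
    samples: pd.DataFrame | None = None,
    reference_isotopologue: int | None = None,
    normalization: str = "per-sample",
) -> pd.DataFrame:
    """Compute the Metabolite Labeling Score table.

    Parameters
    ----------
    corrected
        Corrected distributions (traced samples; see ``samples``).
    policy
        Quality filters; default :class:`FilterPolicy`.
    reference_metabolite
        Metabolite whose label accumulation normalizes each sample
        (default ``"glutamate"``).
    samples
        Optional sample-metadata frame. When given, tracer-free
        (``unlabeled``) samples are excluded from scoring — their near-zero
        reference labeling makes the ratio meaningless; they belong in the
        QC report instead.
    reference_isotopologue
        If given, normalize to FE(M+i) of the reference instead of its total
        labeling.
    normalization
        ``"per-sample"`` (default) divides by the same sample's reference
        labeling; ``"group-mean"`` divides by the mean reference labeling of
        the sample's model system (requires ``samples``).

    Returns
    -------
    DataFrame with one row per metabolite × sample:
    ``metabolite_id, sample_id, total_labeling, pool_size, passed_filters,
    score`` (score is NaN for rows failing filters).
    """
    if policy is None:
        policy = FilterPolicy()
    if normalization not in ("per-sample", "group-mean"):
        raise ValueError("normalization must be 'per-sample' or 'group-mean'")
    if normalization == "group-mean" and samples is None:
        raise ValueError("group-mean normalization requires sample metadata")

    corrected = list(corrected)
    traced_samples: set[str] | None = None
    if samples is not None:
        traced_samples = set(
            samples.loc[samples["tracer_condition"] == "traced", "sample_id"]
        )
        n_dropped = sum(1 for d in corrected if d.sample_id not in traced_samples)
        if n_dropped:
            logger.info(
                "excluding %d tracer-free metabolite×sample rows from scoring",
                n_dropped,
            )
        corrected = [d for d in corrected if d.sample_id in traced_samples]
    if not corrected:
        raise ValueError("no traced distributions to score")

    rows = []
    for dist in corrected:
        tl = np.nan if dist.undetected else total_labeling(dist)
        rows.append((dist.metabolite_id, dist.sample_id, tl, dist.pool_size))
    table = pd.DataFrame(
        rows, columns=["metabolite_id", "sample_id", "total_labeling", "pool_size"]
    )
    dup = table.duplicated(["metabolite_id", "sample_id"])
    if dup.any():
        raise ValueError("duplicate metabolite×sample distributions in input")

    detected = table["pool_size"] > 0
    median_pool = (
        table.loc[detected].groupby("sample_id")["pool_size"].median()
    )
    thresholds = table["sample_id"].map(
        lambda sid: policy.resolve_threshold(float(median_pool.get(sid, 0.0)))
    )
    table["passed_filters"] = (
        detected
        & (table["total_labeling"] > policy.min_total_labeling)
        & (table["pool_size"] >= thresholds)
    )

    # reference labeling per sample
    ref_by_sample: dict[str, float] = {}
    by_key = {(d.metabolite_id, d.sample_id): d for d in corrected}
    for sid in table["sample_id"].unique():
        ref = by_key.get((reference_metabolite, sid))
        if ref is None or ref.undetected:
            raise ValueError(
                f"reference metabolite {reference_metabolite!r} missing or "
                f"undetected in sample {sid!r}"
            )
        if reference_isotopologue is None:
            value = total_labeling(ref)
        else:
            value = fractional_enrichment(ref, reference_isotopologue)
        if value <= 0:
            raise ValueError(
                f"reference metabolite {reference_metabolite!r} has zero "
                f"label accumulation in traced sample {sid!r}"
            )
        ref_by_sample[sid] = value

    if normalization == "group-mean":
        group_of = dict(zip(samples["sample_id"], samples["model_system"]))
        sums: dict[str, list[float]] = {}
        for sid, value in ref_by_sample.items():
            sums.setdefault(group_of[sid], []).append(value)
        group_mean = {g: float(np.mean(v)) for g, v in sums.items()}
        denom = table["sample_id"].map(lambda sid: group_mean[group_of[sid]])
    else:
        denom = table["sample_id"].map(ref_by_sample)

    table["score"] = np.where(
        table["passed_filters"], table["total_labeling"] / denom, np.nan
    )
    return table


def steady_state_ratio(
    pools: Mapping[str, float] | pd.Series,
    numerator_id: str,
    denominator_id: str,
) -> float:
    """Ratio of two metabolites' total pool sizes in one sample.

    A purely steady-state metric on raw total intensities (no labeling
    information), e.g. dihydrouracil/uracil as a pyrimidine-degradation
    marker or argininosuccinate/citrulline for urea-cycle flux.
    """
    if numerator_id not in pools or denominator_id not in pools:
        raise KeyError(
            f"pool sizes required for both {numerator_id!r} and "
            f"{denominator_id!r}"
        )
    denom = float(pools[denominator_id])
    if denom <= 0:
        raise ValueError(
            f"denominator metabolite {denominator_id!r} has zero/undetected pool"
        )
    num = float(pools[numerator_id])
    if num == 0:
        logger.warning(
            "numerator metabolite %r undetected; ratio is 0", numerator_id
        )
    return num / denom


def isotopologue_report(
    corrected: Iterable[CorrectedDistribution],
    metabolite_id: str,
    i: int,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample fractional enrichment of M+i for one metabolite.

    Undetected samples are reported with NaN enrichment. If sample metadata
    is supplied it is joined on for grouping (model system, tracer
    condition, preconditioning).
    """
    rows = []
    for dist in corrected:
        if dist.metabolite_id != metabolite_id:
            continue
        fe = np.nan if dist.undetected else fractional_enrichment(dist, i)
        rows.append((dist.sample_id, fe))
    if not rows:
        raise KeyError(f"no corrected distributions for {metabolite_id!r}")
    report = pd.DataFrame(rows, columns=["sample_id", "fractional_enrichment"])
    report.insert(0, "metabolite_id", metabolite_id)
    report.insert(2, "isotopologue", i)
    if samples is not None:
        report = report.merge(samples, on="sample_id", how="left")
    return report
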