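"""Differential labeling between model systems and condition concordance.

Volcano-style comparison of Metabolite Labeling Scores between two groups:
per metabolite, an unpaired two-sample t-test (Welch by default, pooled
optionally) with a fold-change of group means, gated at p < 0.05 and
fold-change > 1.25 by default. Metabolites quantifiable in only one group
are reported as categorical "exclusive" records (the tracing analogue of
"not detected") rather than given pseudo-infinite fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConcordanceResult",
    "TWO_GROUP_TESTS",
    "compare_models",
    "concordance",
    "paired_metabolite_test",
]

TWO_GROUP_TESTS = ("welch", "pooled")

_TINY_P = float(np.finfo(float).tiny)


def _two_sample_t(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float, float]:
    """Two-tailed unpaired t-test of b vs a, safe against zero variance."""
    if test not in TWO_GROUP_TESTS:
        raise ValueError(f"test must be one of {TWO_GROUP_TESTS}, got {test!r}")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(b) - np.mean(a)) * np.inf), _TINY_P
    t, p = stats.ttest_ind(b, a, equal_var=(test == "pooled"))
    return float(t), float(p)


def _passing_scores(scores: pd.DataFrame, sample_ids: Collection[str]) -> pd.DataFrame:
    mask = scores["sample_id"].isin(set(sample_ids)) & scores["passed_filters"]
    return scores.loc[mask]


def compare_models(
    scores: pd.DataFrame,
    group_a: Collection[str],
    group_b: Collection[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 1.25,
    test: str = "welch",
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Volcano comparison of labeling scores between two sample groups.

    Parameters
    ----------
    scores
        Labeling-score table from
        :func:`~tracescore.scoring.compute_labeling_scores`.
    group_a, group_b
        Disjoint collections of traced sample ids. Fold change is reported
        as B relative to A.
    p_threshold, fc_threshold
        Significance gates: two-tailed p < ``p_threshold`` AND
        max(FC, 1/FC) > ``fc_threshold``.
    test
        ``"welch"`` (default, unequal variances) or ``"pooled"``.

    Returns
    -------
    DataFrame with one row per metabolite, sorted by p ascending (ties by
    |log2FC| descending, then metabolite id), with columns
    ``metabolite_id, n_A, n_B, mean_score_A, mean_score_B, fold_change,
    log2_fold_change, t_statistic, p_value, q_value, status, significant``.
    Status is ``tested``, ``exclusive_to_A``/``exclusive_to_B`` (scored in
    >= ``min_replicates`` samples of one group but fewer in the other), or
    ``filtered``.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    known = set(scores["sample_id"])
    missing = (set(group_a) | set(group_b)) - known
    if missing:
        raise ValueError(f"group samples absent from score table: {sorted(missing)}")

    a_scores = _passing_scores(scores, group_a)
    b_scores = _passing_scores(scores, group_b)
    a_by_met = {m: g["score"].to_numpy() for m, g in a_scores.groupby("metabolite_id")}
    b_by_met = {m: g["score"].to_numpy() for m, g in b_scores.groupby("metabolite_id")}

    records = []
    all_mets = sorted(
        set(scores.loc[scores["sample_id"].isin(group_a + group_b), "metabolite_id"])
    )
    for met in all_mets:
        a = a_by_met.get(met, np.empty(0))
        b = b_by_met.get(met, np.empty(0))
        n_a, n_b = len(a), len(b)
        rec = {
            "metabolite_id": met,
            "n_A": n_a,
            "n_B": n_b,
            "mean_score_A": float(np.mean(a)) if n_a else np.nan,
            "mean_score_B": float(np.mean(b)) if n_b else np.nan,
            "fold_change": np.nan,
            "log2_fold_change": np.nan,
            "t_statistic": np.nan,
            "p_value": np.nan,
            "status": "filtered",
            "significant": False,
        }
        if n_a >= min_replicates and n_b >= min_replicates:
            t, p = _two_sample_t(a, b, test)
            fc = rec["mean_score_B"] / rec["mean_score_A"]
            rec.update(
                fold_change=fc,
                log2_fold_change=float(np.log2(fc)) if fc > 0 else np.nan,
                t_statistic=t,
                p_value=p,
                status="tested",
                significant=bool(
                    p < p_threshold and max(fc, 1.0 / fc) > fc_threshold
                ),
            )
        elif n_a >= min_replicates and n_b < min_replicates:
            rec["status"] = "exclusive_to_A"
            rec["significant"] = True
        elif n_b >= min_replicates and n_a < min_replicates:
            rec["status"] = "exclusive_to_B"
            rec["significant"] = True
        records.append(rec)

    result = pd.DataFrame.from_records(records)
    tested = result["status"] == "tested"
    result["q_value"] = np.nan
    if tested.any():
        result.loc[tested, "q_value"] = multipletests(
            result.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    result["_abs_lfc"] = result["log2_fold_change"].abs()
    result = result.sort_values(
        ["p_value", "_abs_lfc", "metabolite_id"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_abs_lfc")
    return result.reset_index(drop=True)


@dataclass(frozen=True)
class ConcordanceResult:
    """OLS + Pearson concordance of labeling between two conditions."""

    r: float
    r_squared: float
    slope: float
    intercept: float
    regression_p_value: float
    n_points: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "r": self.r,
                    "r_squared": self.r_squared,
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "p_value": self.regression_p_value,
                    "n_points": self.n_points,
                }
            ]
        )


def concordance(
    scores_x: pd.Series | Mapping[str, float],
    scores_y: pd.Series | Mapping[str, float],
) -> ConcordanceResult:
    """Per-metabolite labeling concordance between two conditions.

    Inner-joins the two per-metabolite series, regresses y on x by ordinary
    least squares, and reports Pearson's r, r², slope, intercept and the
    two-tailed p-value for slope ≠ 0.
    """
    x = pd.Series(scores_x, dtype=float)
    y = pd.Series(scores_y, dtype=float)
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(
            f"concordance needs >= 3 shared metabolites, got {len(joined)}"
        )
    if np.var(joined["x"].to_numpy()) == 0:
        raise ValueError("zero variance in x; regression undefined")
    fit = stats.linregress(joined["x"], joined["y"])
    return ConcordanceResult(
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        regression_p_value=float(fit.pvalue),
        n_points=len(joined),
    )


@dataclass(frozen=True)
class GroupTestResult:
    """Result of a one-way ANOVA or two-sample t-test on one metabolite."""

    metabolite_id: str
    design: str
    statistic: float
    p_value: float
    group_means: Mapping[str, float]


def paired_metabolite_test(
    scores: pd.DataFrame,
    metabolite_id: str,
    groups: Mapping[str, Sequence[str]],
    design: str = "auto",
) -> GroupTestResult:
    """Figure-panel style test of one metabolite's scores across groups.

    Two groups are compared by the unpaired t-test (matching
    :func:`compare_models`); three or more by one-way ANOVA.
    """
    if design not in ("auto", "one_way_anova", "t_test"):
        raise ValueError(f"unknown design {design!r}")
    values: dict[str, np.ndarray] = {}
    met_scores = scores.loc[
        (scores["metabolite_id"] == metabolite_id) & scores["passed_filters"]
    ]
    by_sample = dict(zip(met_scores["sample_id"], met_scores["score"]))
    for name, sample_ids in groups.items():
        vals = np.array([by_sample[s] for s in sample_ids if s in by_sample])
        if len(vals) < 2:
            raise ValueError(
                f"group {name!r} has {len(vals)} scored replicates for "
                f"{metabolite_id!r}; need >= 2"
            )
        values[name] = vals
    if len(values) < 2:
        raise ValueError("need >= 2 groups")
    if design == "t_test" and len(values) != 2:
        raise ValueError("t_test design requires exactly 2 groups")
    means = {name: float(np.mean(v)) for name, v in values.items()}
    if len(values) == 2 and design in ("auto", "t_test"):
        (a, b) = values.values()
        t, p = _two_sample_t(a, b, "welch")
        return GroupTestResult(metabolite_id, "t_test", t, p, means)
    f, p = stats.f_oneway(*values.values())
    return GroupTestResult(metabolite_id, "one_way_anova", float(f), float(p), means)
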