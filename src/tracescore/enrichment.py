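"""Quantitative metabolite-set enrichment analysis (QEA) by permutation.

Set-level test of association between Metabolite Labeling Scores and group
membership. The set statistic is the mean squared two-sample t-statistic of
the set's members between groups — a quadratic association statistic in the
spirit of globaltest-style QEA. The null distribution permutes sample group
labels jointly across all metabolites, preserving inter-metabolite
correlation. When the number of distinct label splits C(n_A+n_B, n_A) is
small (<= 10000) the splits are enumerated exhaustively and p-values are
exact multiples of 1/#splits; otherwise Monte Carlo with the add-one rule
p = (1 + #{perm >= obs}) / (1 + n_permutations).
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import MetaboliteSet

logger = logging.getLogger(__name__)

__all__ = ["run_qea"]


def _squared_t_matrix(
    values: np.ndarray, in_a: np.ndarray, n_a: int, n_b: int, pooled: bool
) -> np.ndarray:
    """Squared two-sample t for every metabolite (rows) × split (columns).

    ``values`` is (m, S); ``in_a`` is (S, P) boolean membership of each
    sample in group A for each of P splits.
    """
    z = in_a.astype(float)
    w = 1.0 - z
    sum_a = values @ z
    sum_b = values @ w
    sumsq_a = (values**2) @ z
    sumsq_b = (values**2) @ w
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = (sumsq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (sumsq_b - n_b * mean_b**2) / (n_b - 1)
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    if pooled:
        pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        denom = pooled_var * (1.0 / n_a + 1.0 / n_b)
    else:
        denom = var_a / n_a + var_b / n_b
    diff2 = (mean_a - mean_b) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff2 / denom
    t2[diff2 == 0.0] = 0.0
    t2[(diff2 > 0.0) & (denom == 0.0)] = np.inf
    return t2


def run_qea(
    scores: pd.DataFrame,
    sets: Sequence[MetaboliteSet],
    group_a: Collection[str],
    group_b: Collection[str],
    n_permutations: int = 9999,
    seed: int = 0,
    test: str = "welch",
    exhaustive_limit: int = 10000,
    synonyms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation quantitative enrichment analysis on labeling scores.

    Parameters
    ----------
    scores
        Labeling-score table (taken as-is — no additional normalization,
        filtering or scaling beyond the score's own quality filters).
    sets
        Metabolite sets; member names are matched case-insensitively, with
        an optional ``synonyms`` map (alias -> measured metabolite id).
    group_a, group_b
        Disjoint traced sample-id collections.
    n_permutations, seed
        Monte Carlo settings; ignored when exhaustive enumeration applies.

    Returns
    -------
    DataFrame sorted by (p ascending, statistic descending) with columns
    ``set_name, n_members_tested, set_statistic, p_value, q_value, status,
    members_tested``. Sets without testable members get status
    ``untestable``. Members are testable when they carry a score in every
    sample of both groups, so the joint label permutation is exact.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    n_a, n_b = len(group_a), len(group_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 samples")
    order = group_a + group_b

    wide = scores.pivot(index="metabolite_id", columns="sample_id", values="score")
    missing = set(order) - set(wide.columns)
    if missing:
        raise ValueError(f"group samples absent from score table: {sorted(missing)}")
    wide = wide[order]
    complete = wide.dropna()
    testable_ids = list(complete.index)
    values = complete.to_numpy(dtype=float)

    lookup: dict[str, str] = {}
    for met in testable_ids:
        key = met.strip().lower()
        if key in lookup and lookup[key] != met:
            logger.warning("case-insensitive name collision for %r", met)
        lookup[key] = met
    if synonyms:
        for alias, target in synonyms.items():
            key = target.strip().lower()
            if key in lookup:
                lookup[alias.strip().lower()] = lookup[key]

    row_of = {met: i for i, met in enumerate(testable_ids)}

    n_splits = comb(n_a + n_b, n_a)
    exhaustive = n_splits <= exhaustive_limit
    if exhaustive:
        logger.info(
            "exhaustive permutation: enumerating all %d label splits", n_splits
        )
        in_a = np.zeros((n_a + n_b, n_splits), dtype=bool)
        for k, idx in enumerate(combinations(range(n_a + n_b), n_a)):
            in_a[list(idx), k] = True
    else:
        rng = np.random.default_rng(seed)
        in_a = np.zeros((n_a + n_b, n_permutations + 1), dtype=bool)
        in_a[:n_a, 0] = True  # observed labeling first
        for k in range(1, n_permutations + 1):
            in_a[rng.permutation(n_a + n_b)[:n_a], k] = True

    if values.shape[0]:
        t2 = _squared_t_matrix(values, in_a, n_a, n_b, pooled=(test == "pooled"))
    else:
        t2 = np.zeros((0, in_a.shape[1]))
    observed_col = 0 if not exhaustive else None
    if exhaustive:
        # locate the observed split (first n_a samples in group A)
        observed_split = tuple(range(n_a))
        for k, idx in enumerate(combinations(range(n_a + n_b), n_a)):
            if idx == observed_split:
                observed_col = k
                break

    records = []
    for s in sets:
        matched_rows = []
        matched_ids = []
        unmatched = []
        for member in s.member_ids:
            met = lookup.get(member.strip().lower())
            if met is None:
                unmatched.append(member)
            else:
                matched_rows.append(row_of[met])
                matched_ids.append(met)
        if unmatched:
            logger.warning(
                "set %r: %d member(s) not matched to scored metabolites: %s",
                s.set_name,
                len(unmatched),
                ", ".join(unmatched),
            )
        if not matched_rows:
            records.append(
                {
                    "set_name": s.set_name,
                    "n_members_tested": 0,
                    "set_statistic": np.nan,
                    "p_value": np.nan,
                    "status": "untestable",
                    "members_tested": "",
                }
            )
            continue
        set_stats = t2[matched_rows].mean(axis=0)
        observed = set_stats[observed_col]
        if exhaustive:
            p = float(np.sum(set_stats >= observed - 1e-12) / n_splits)
        else:
            exceed = int(np.sum(set_stats[1:] >= observed - 1e-12))
            p = (1.0 + exceed) / (1.0 + n_permutations)
        records.append(
            {
                "set_name": s.set_name,
                "n_members_tested": len(matched_rows),
                "set_statistic": float(observed),
                "p_value": p,
                "status": "tested",
                "members_tested": ";".join(matched_ids),
            }
        )

    result = pd.DataFrame.from_records(records)
    tested = result["status"] == "tested"
    result["q_value"] = np.nan
    if tested.any():
        result.loc[tested, "q_value"] = multipletests(
            result.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    result = result.sort_values(
        ["p_value", "set_statistic", "set_name"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return result[
        [
            "set_name",
            "n_members_tested",
            "set_statistic",
            "p_value",
            "q_value",
            "status",
            "members_tested",
        ]
    ]
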