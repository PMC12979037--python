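"""Independent brute-force oracles used by the test suite.

These enumerate probability spaces directly (itertools over atom isotope
states, recursive enumeration of precursor molecule states) and share no
code with the library's closed-form convolution / vectorized machinery.
"""

from __future__ import annotations

import itertools
from math import prod

import numpy as np

from tracescore.io import MoleculeSpec
from tracescore.simulate import NetworkSpec


def enumeration_correction_matrix(
    spec: MoleculeSpec,
    abundances: dict[str, tuple[tuple[int, float], ...]],
    mode: str,
) -> np.ndarray:
    """Correction matrix by enumerating every atom's isotope state.

    For column j, the n-j unlabeled tracer atoms (plus, in all-elements
    mode, every non-tracer atom of the formula) each independently take one
    of their element's isotope states; molecules are binned by total mass
    shift, truncated at shift n.
    """
    n = spec.tracer_atom_count
    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        atoms: list[tuple[tuple[int, float], ...]] = [
            abundances[spec.tracer_element]
        ] * (n - j)
        if mode == "all-elements":
            for element, count in spec.formula.items():
                extra = int(count) - (n if element == spec.tracer_element else 0)
                atoms.extend([abundances[element]] * extra)
        if not atoms:
            matrix[j, j] = 1.0
            continue
        for combo in itertools.product(*atoms):
            shift = sum(s for s, _ in combo)
            if j + shift <= n:
                matrix[j + shift, j] += prod(p for _, p in combo)
    return matrix


def enumeration_label_distribution(
    network: NetworkSpec, activity: dict[str, float] | None = None
) -> dict[str, dict[int, float]]:
    """Joint position-label distributions by explicit enumeration.

    For each metabolite, in topological order, enumerates all combinations
    of precursor molecule states (one state per source draw) and accumulates
    the probability of every resulting product configuration.
    """
    activity = dict(activity or {})
    by_id = network.by_id
    rule_of = network.rule_of
    joints: dict[str, dict[int, float]] = {}
    for mid in network.topological_order():
        k = by_id[mid].spec.tracer_atom_count
        if mid == network.tracer.metabolite_id:
            entry = network.tracer
            dist: dict[int, float] = {}
            if entry.mode == "joint":
                dist[0] = dist.get(0, 0.0) + (1.0 - entry.enrichment)
                full = (1 << k) - 1
                dist[full] = dist.get(full, 0.0) + entry.enrichment
            else:
                for state in range(1 << k):
                    bits = bin(state).count("1")
                    dist[state] = entry.enrichment**bits * (
                        1.0 - entry.enrichment
                    ) ** (k - bits)
            joints[mid] = dist
            continue
        rule = rule_of.get(mid)
        if rule is None:
            joints[mid] = {0: 1.0}
            continue
        eff = rule.fraction_new * activity.get(rule.pathway, 1.0)
        eff = min(max(eff, 0.0), 1.0)
        new: dict[int, float] = {}
        draw_states = [
            list(joints[d.precursor_id].items()) for d in rule.draws
        ]
        for combo in itertools.product(*draw_states):
            state = 0
            probability = 1.0
            for draw, (prec_state, prob) in zip(rule.draws, combo):
                probability *= prob
                for p_pos, q_pos in draw.position_map.items():
                    if prec_state >> q_pos & 1:
                        state |= 1 << p_pos
            new[state] = new.get(state, 0.0) + probability
        pool = {state: eff * p for state, p in new.items() if eff * p > 0.0}
        pool[0] = pool.get(0, 0.0) + (1.0 - eff)
        joints[mid] = pool
    return joints


def anova_f_oracle(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F by the textbook sum-of-squares decomposition."""
    grand = np.concatenate(groups).mean()
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n_total - k))
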