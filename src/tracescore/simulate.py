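"""Synthetic ¹⁵N₂-glutamine tracing datasets for testing the pipeline.

Simulates steady-state label propagation through a small nitrogen-transfer
network. Each metabolite carries a set of nitrogen positions; a transfer
rule says which precursor position feeds each product position. Labeling is
propagated in topological order as a joint distribution over position-label
configurations, and the pool of each metabolite is a steady-state
"fraction-new" mixture: a fraction of the pool was synthesized from labeled
precursors during the tracing window, the rest is pre-existing unlabeled
material. Group-specific pathway-activity multipliers scale the fraction-new
of tagged reactions, creating differential labeling between model systems.

Measured spectra are produced by forward-convolving the true isotopologue
distribution with all-element natural abundance, scaling by pool size and
applying multiplicative lognormal replicate noise. Ground truth (true
fractions, total labeling, glutamate-normalized score, differential flags)
is always emitted alongside the data.

The preset networks use textbook nitrogen atom mappings and are pedagogical
fixtures, not quantitative mechanistic models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from graphlib import CycleError, TopologicalSorter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correction import _cached_matrix
from .io import MoleculeSpec, MetaboliteSet, TracingDataset, parse_formula

__all__ = [
    "SourceDraw",
    "TransferRule",
    "TracerEntry",
    "NetworkMetabolite",
    "NetworkSpec",
    "GroupSpec",
    "ScenarioConfig",
    "SimulationResult",
    "simulate_dataset",
    "preset_scenario",
    "preset_metabolite_sets",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SourceDraw:
    """One precursor molecule drawn during synthesis of one product molecule.

    ``position_map`` maps product nitrogen positions to positions of this
    precursor molecule. Positions drawn from the same molecule stay
    correlated (an intact purine ring keeps its labels together); separate
    draws are independent (two transamidation events use two glutamines).
    """

    precursor_id: str
    position_map: Mapping[int, int]


@dataclass(frozen=True)
class TransferRule:
    """Synthesis route of one product from labeled precursors.

    Product positions absent from every draw are filled from the unlabeled
    pool. ``fraction_new`` is the steady-state fraction of the product pool
    synthesized through this route during the tracing window, before any
    pathway-activity multiplier.
    """

    product_id: str
    draws: tuple[SourceDraw, ...]
    fraction_new: float
    pathway: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_new <= 1.0:
            raise ValueError(
                f"{self.product_id}: fraction_new must be in [0, 1]"
            )
        seen: set[int] = set()
        for draw in self.draws:
            for pos in draw.position_map:
                if pos in seen:
                    raise ValueError(
                        f"{self.product_id}: product position {pos} mapped "
                        "from more than one precursor position"
                    )
                seen.add(pos)


@dataclass(frozen=True)
class TracerEntry:
    """Labeled tracer entering the network (¹⁵N₂-glutamine by default).

    ``mode="joint"`` labels all positions of a molecule together (a pure
    M+2 tracer diluted by unlabeled molecules); ``"independent"`` labels
    each position independently with probability ``enrichment``.
    """

    metabolite_id: str = "glutamine"
    enrichment: float = 0.7
    mode: str = "joint"

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("tracer enrichment must be in [0, 1]")
        if self.mode not in ("joint", "independent"):
            raise ValueError(f"unknown tracer mode {self.mode!r}")


@dataclass(frozen=True)
class NetworkMetabolite:
    spec: MoleculeSpec
    base_pool: float

    def __post_init__(self) -> None:
        if self.base_pool < 0:
            raise ValueError(f"{self.spec.metabolite_id}: negative base pool")


@dataclass(frozen=True)
class NetworkSpec:
    """A steady-state nitrogen-transfer network."""

    metabolites: tuple[NetworkMetabolite, ...]
    rules: tuple[TransferRule, ...]
    tracer: TracerEntry = field(default_factory=TracerEntry)

    def __post_init__(self) -> None:
        ids = [m.spec.metabolite_id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids in network")
        by_id = {m.spec.metabolite_id: m for m in self.metabolites}
        if self.tracer.metabolite_id not in by_id:
            raise ValueError(
                f"tracer metabolite {self.tracer.metabolite_id!r} not in network"
            )
        products = [r.product_id for r in self.rules]
        if len(set(products)) != len(products):
            raise ValueError("a product may have at most one transfer rule")
        for rule in self.rules:
            if rule.product_id not in by_id:
                raise ValueError(f"unknown product {rule.product_id!r}")
            n_prod = by_id[rule.product_id].spec.tracer_atom_count
            for draw in rule.draws:
                if draw.precursor_id not in by_id:
                    raise ValueError(
                        f"{rule.product_id}: unknown precursor "
                        f"{draw.precursor_id!r}"
                    )
                n_prec = by_id[draw.precursor_id].spec.tracer_atom_count
                for p_pos, q_pos in draw.position_map.items():
                    if not 0 <= p_pos < n_prod:
                        raise ValueError(
                            f"{rule.product_id}: product position {p_pos} "
                            f"out of range"
                        )
                    if not 0 <= q_pos < n_prec:
                        raise ValueError(
                            f"{rule.product_id}: precursor position {q_pos} "
                            f"out of range for {draw.precursor_id}"
                        )
        self.topological_order()  # raises on cycles

    @property
    def by_id(self) -> dict[str, NetworkMetabolite]:
        return {m.spec.metabolite_id: m for m in self.metabolites}

    @property
    def rule_of(self) -> dict[str, TransferRule]:
        return {r.product_id: r for r in self.rules}

    def topological_order(self) -> list[str]:
        sorter: TopologicalSorter = TopologicalSorter()
        rule_of = {r.product_id: r for r in self.rules}
        for met in self.metabolites:
            mid = met.spec.metabolite_id
            rule = rule_of.get(mid)
            deps = {d.precursor_id for d in rule.draws} if rule else set()
            sorter.add(mid, *sorted(deps))
        try:
            return list(sorter.static_order())
        except CycleError as err:
            raise ValueError(f"transfer network contains a cycle: {err}") from err


@dataclass(frozen=True)
class GroupSpec:
    """One model-system group in a scenario."""

    name: str
    n_traced: int = 3
    n_unlabeled: int = 0
    activity: Mapping[str, float] = field(default_factory=dict)
    pool_scale: Mapping[str, float] = field(default_factory=dict)
    precondition_hours: float = 120.0

    def __post_init__(self) -> None:
        if self.n_traced < 0 or self.n_unlabeled < 0:
            raise ValueError("replicate counts must be >= 0")
        for tag, mult in self.activity.items():
            if mult < 0:
                raise ValueError(f"{self.name}: negative activity for {tag!r}")
        for mid, scale in self.pool_scale.items():
            if scale < 0:
                raise ValueError(f"{self.name}: negative pool scale for {mid!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions: groups, replicate noise and seed.

    ``noise_cv`` is the lognormal coefficient of variation of the shared
    per-(metabolite, sample) intensity factor (pool/injection variability);
    isotopologue entries additionally receive independent lognormal noise
    with CV ``noise_cv * isotopologue_noise_frac``, reflecting that
    isotopologue ratios are measured far more precisely than absolute
    intensities on LC-MS.
    """

    groups: tuple[GroupSpec, ...]
    noise_cv: float = 0.10
    isotopologue_noise_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.isotopologue_noise_frac < 0:
            raise ValueError("noise parameters must be >= 0")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")


# -- label propagation ------------------------------------------------------


def _tracer_joint(k: int, entry: TracerEntry) -> np.ndarray:
    dist = np.zeros(2**k)
    if entry.mode == "joint":
        dist[0] = 1.0 - entry.enrichment
        dist[2**k - 1] += entry.enrichment
    else:
        for state in range(2**k):
            bits = bin(state).count("1")
            dist[state] = entry.enrichment**bits * (1 - entry.enrichment) ** (
                k - bits
            )
    return dist


def _marginalize(joint: np.ndarray, positions: Sequence[int]) -> np.ndarray:
    """Marginal joint distribution over a subset of positions."""
    out = np.zeros(2 ** len(positions))
    for state, prob in enumerate(joint):
        if prob == 0.0:
            continue
        sub = 0
        for i, pos in enumerate(positions):
            if state >> pos & 1:
                sub |= 1 << i
        out[sub] += prob
    return out


def propagate_labels(
    network: NetworkSpec, activity: Mapping[str, float] | None = None
) -> dict[str, np.ndarray]:
    """Joint position-label distribution of every metabolite pool at steady state.

    Returns, per metabolite, an array of length ``2**k`` (k = tracer atom
    count) over labeling configurations, bit ``i`` = position ``i`` labeled.
    """
    activity = dict(activity or {})
    by_id = network.by_id
    rule_of = network.rule_of
    joints: dict[str, np.ndarray] = {}
    for mid in network.topological_order():
        k = by_id[mid].spec.tracer_atom_count
        if mid == network.tracer.metabolite_id:
            joints[mid] = _tracer_joint(k, network.tracer)
            continue
        rule = rule_of.get(mid)
        pool = np.zeros(2**k)
        if rule is None:
            pool[0] = 1.0
            joints[mid] = pool
            continue
        eff = rule.fraction_new * activity.get(rule.pathway, 1.0)
        eff = float(min(max(eff, 0.0), 1.0))
        # joint distribution of a newly synthesized molecule
        new = np.zeros(2**k)
        new[0] = 1.0
        for draw in rule.draws:
            q_positions = list(draw.position_map.values())
            p_positions = list(draw.position_map.keys())
            marg = _marginalize(joints[draw.precursor_id], q_positions)
            combined = np.zeros(2**k)
            for state, prob in enumerate(new):
                if prob == 0.0:
                    continue
                for sub, sub_prob in enumerate(marg):
                    if sub_prob == 0.0:
                        continue
                    extra = 0
                    for i, p_pos in enumerate(p_positions):
                        if sub >> i & 1:
                            extra |= 1 << p_pos
                    combined[state | extra] += prob * sub_prob
            new = combined
        pool = eff * new
        pool[0] += 1.0 - eff
        joints[mid] = pool
    return joints


def isotopologue_distribution(joint: np.ndarray) -> np.ndarray:
    """Collapse a joint position distribution to M+i fractions by label count."""
    k = int(math.log2(len(joint)))
    out = np.zeros(k + 1)
    for state, prob in enumerate(joint):
        out[bin(state).count("1")] += prob
    return out


# -- dataset generation ------------------------------------------------------


@dataclass
class SimulationResult:
    """A simulated raw dataset plus its ground truth."""

    dataset: TracingDataset
    truth: pd.DataFrame
    network: NetworkSpec
    scenario: ScenarioConfig


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_dataset(
    network: NetworkSpec,
    scenario: ScenarioConfig,
    seed: int | None = None,
) -> SimulationResult:
    """Simulate raw isotopologue intensities for a scenario.

    Per group: propagate labels through the network with the group's
    pathway-activity multipliers; per replicate: forward-convolve the true
    distributions with all-element natural abundance, scale by pool size and
    apply lognormal noise. Tracer-free replicates carry no label. Ground
    truth is emitted per group × metabolite × isotopologue.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    by_id = network.by_id
    order = network.topological_order()
    specs = {mid: by_id[mid].spec for mid in order}
    forward = {
        mid: _cached_matrix(spec, "all-elements").matrix
        for mid, spec in specs.items()
    }

    unlabeled_truth = {
        mid: np.eye(spec.tracer_atom_count + 1)[0] for mid, spec in specs.items()
    }

    sample_rows = []
    intensity_rows: list[tuple[str, str, int, float]] = []
    truth_rows = []

    group_tl: dict[str, dict[str, float]] = {}
    group_fracs: dict[str, dict[str, np.ndarray]] = {}
    for group in scenario.groups:
        joints = propagate_labels(network, group.activity)
        fracs = {mid: isotopologue_distribution(joints[mid]) for mid in order}
        group_fracs[group.name] = fracs
        group_tl[group.name] = {mid: float(1.0 - f[0]) for mid, f in fracs.items()}

    tl_table = pd.DataFrame(group_tl)  # metabolite × group
    detect_table = pd.DataFrame(
        {
            g.name: {mid: g.pool_scale.get(mid, 1.0) > 0 for mid in order}
            for g in scenario.groups
        }
    )
    differential = {
        mid: bool(
            (tl_table.loc[mid].max() - tl_table.loc[mid].min()) > 1e-12
            or detect_table.loc[mid].nunique() > 1
        )
        for mid in order
    }

    for group in scenario.groups:
        fracs = group_fracs[group.name]
        ref_tl_glutamate = group_tl[group.name].get("glutamate", np.nan)
        for mid in order:
            spec = specs[mid]
            rule = network.rule_of.get(mid)
            detectable = group.pool_scale.get(mid, 1.0) > 0
            tl = group_tl[group.name][mid]
            score = (
                tl / ref_tl_glutamate
                if ref_tl_glutamate and not math.isnan(ref_tl_glutamate)
                else np.nan
            )
            for i, f in enumerate(fracs[mid]):
                truth_rows.append(
                    {
                        "group": group.name,
                        "metabolite_id": mid,
                        "isotopologue": i,
                        "true_fraction": float(f),
                        "true_total_labeling": tl,
                        "true_score": score,
                        "detectable": detectable,
                        "pathway": rule.pathway if rule else None,
                        "differential": differential[mid],
                    }
                )

        conditions = [("traced", group.n_traced), ("unlabeled", group.n_unlabeled)]
        for condition, n_reps in conditions:
            for rep in range(1, n_reps + 1):
                sid = f"{group.name}_{condition}_{rep}"
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "model_system": group.name,
                        "tracer_condition": condition,
                        "precondition_hours": group.precondition_hours,
                        "replicate": rep,
                    }
                )
                for mid in order:
                    spec = specs[mid]
                    n = spec.tracer_atom_count
                    pool = by_id[mid].base_pool * group.pool_scale.get(mid, 1.0)
                    true = (
                        fracs[mid] if condition == "traced" else unlabeled_truth[mid]
                    )
                    measured = forward[mid] @ true
                    shared = _lognormal_factors(rng, scenario.noise_cv, ())
                    iso_noise = _lognormal_factors(
                        rng,
                        scenario.noise_cv * scenario.isotopologue_noise_frac,
                        n + 1,
                    )
                    intensities = pool * measured * float(shared) * iso_noise
                    for i in range(n + 1):
                        intensity_rows.append((mid, sid, i, float(intensities[i])))

    intensities_df = pd.DataFrame(
        intensity_rows,
        columns=["metabolite_id", "sample_id", "isotopologue", "intensity"],
    )
    metabolites_df = pd.DataFrame(
        [
            {
                "metabolite_id": mid,
                "formula": _formula_text(specs[mid]),
                "tracer_atom_count": specs[mid].tracer_atom_count,
                "tracer_element": specs[mid].tracer_element,
            }
            for mid in order
        ]
    )
    samples_df = pd.DataFrame(sample_rows)
    dataset = TracingDataset.from_frames(intensities_df, metabolites_df, samples_df)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(dataset, truth, network, scenario)


def _formula_text(spec: MoleculeSpec) -> str:
    from .io import write_formula

    return write_formula(spec.formula)


# -- presets -----------------------------------------------------------------


def _met(mid: str, formula: str, n: int, pool: float) -> NetworkMetabolite:
    return NetworkMetabolite(
        MoleculeSpec(mid, parse_formula(formula), n), base_pool=pool
    )


def _rule(
    product: str,
    fraction_new: float,
    pathway: str | None,
    *draws: tuple[str, Mapping[int, int]],
) -> TransferRule:
    return TransferRule(
        product,
        tuple(SourceDraw(pid, dict(pmap)) for pid, pmap in draws),
        fraction_new,
        pathway,
    )


def _glutamine_network() -> NetworkSpec:
    """Pedagogical ¹⁵N transfer network from glutamine into nucleotides.

    Position conventions: glutamine 0 = amine, 1 = amide; purine-ring
    positions are listed in synthesis order, not IUPAC numbering.
    """
    metabolites = (
        _met("glutamine", "C5H10N2O3", 2, 1.0e6),
        _met("glutamate", "C5H9NO4", 1, 2.0e6),
        _met("aspartate", "C4H7NO4", 1, 5.0e5),
        _met("alanine", "C3H7NO2", 1, 8.0e5),
        _met("serine", "C3H7NO3", 1, 4.0e5),
        _met("glycine", "C2H5NO2", 1, 3.0e5),
        _met("proline", "C5H9NO2", 1, 2.0e5),
        _met("asparagine", "C4H8N2O3", 2, 1.0e5),
        _met("IMP", "C10H13N4O8P", 4, 2.0e5),
        _met("AMP", "C10H14N5O7P", 5, 3.0e5),
        _met("GMP", "C10H14N5O8P", 5, 2.5e5),
        _met("adenosine", "C10H13N5O4", 5, 5.0e4),
        _met("inosine", "C10H12N4O5", 4, 6.0e4),
        _met("hypoxanthine", "C5H4N4O", 4, 4.0e4),
        _met("GDP-mannose", "C16H25N5O16P2", 5, 8.0e4),
        _met("UMP", "C9H13N2O9P", 2, 2.0e5),
        _met("uridine", "C9H12N2O6", 2, 8.0e4),
        _met("uracil", "C4H4N2O2", 2, 5.0e4),
        _met("dihydrouracil", "C4H6N2O2", 2, 3.0e4),
        _met("citrulline", "C6H13N3O3", 3, 1.0e5),
        _met("argininosuccinate", "C10H18N4O6", 4, 2.0e4),
    )
    rules = (
        _rule("glutamate", 0.6, "glutamate_synthesis", ("glutamine", {0: 0})),
        _rule("aspartate", 0.5, "transamination", ("glutamate", {0: 0})),
        _rule("alanine", 0.5, "transamination", ("glutamate", {0: 0})),
        _rule("serine", 0.4, "serine_synthesis", ("glutamate", {0: 0})),
        _rule("glycine", 0.8, "glycine_synthesis", ("serine", {0: 0})),
        _rule("proline", 0.5, "proline_synthesis", ("glutamate", {0: 0})),
        _rule(
            "asparagine",
            0.4,
            "asparagine_synthesis",
            ("aspartate", {0: 0}),
            ("glutamine", {1: 1}),
        ),
        _rule(
            "IMP",
            0.5,
            "purine_synthesis",
            ("aspartate", {0: 0}),
            ("glutamine", {1: 1}),
            ("glutamine", {2: 1}),
            ("glycine", {3: 0}),
        ),
        _rule(
            "AMP",
            0.7,
            "purine_synthesis",
            ("IMP", {0: 0, 1: 1, 2: 2, 3: 3}),
            ("aspartate", {4: 0}),
        ),
        _rule(
            "GMP",
            0.7,
            "purine_synthesis",
            ("IMP", {0: 0, 1: 1, 2: 2, 3: 3}),
            ("glutamine", {4: 1}),
        ),
        _rule(
            "adenosine",
            0.5,
            "purine_degradation",
            ("AMP", {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}),
        ),
        _rule("inosine", 0.5, "purine_degradation", ("IMP", {0: 0, 1: 1, 2: 2, 3: 3})),
        _rule(
            "hypoxanthine",
            0.5,
            "purine_degradation",
            ("inosine", {0: 0, 1: 1, 2: 2, 3: 3}),
        ),
        _rule(
            "GDP-mannose",
            0.5,
            "gdp_mannose_synthesis",
            ("GMP", {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}),
        ),
        _rule(
            "UMP",
            0.6,
            "pyrimidine_synthesis",
            ("glutamine", {0: 1}),
            ("aspartate", {1: 0}),
        ),
        _rule("uridine", 0.4, "pyrimidine_synthesis", ("UMP", {0: 0, 1: 1})),
        _rule("uracil", 0.5, "pyrimidine_degradation", ("uridine", {0: 0, 1: 1})),
        _rule(
            "dihydrouracil", 0.6, "pyrimidine_degradation", ("uracil", {0: 0, 1: 1})
        ),
        _rule(
            "citrulline",
            0.3,
            "urea_cycle",
            ("glutamate", {0: 0}),
            ("glutamate", {1: 0}),
            ("glutamine", {2: 1}),
        ),
        _rule(
            "argininosuccinate",
            0.3,
            "urea_cycle",
            ("citrulline", {0: 0, 1: 1, 2: 2}),
            ("aspartate", {3: 0}),
        ),
    )
    return NetworkSpec(metabolites, rules, TracerEntry("glutamine", 0.7, "joint"))


PRESET_NAMES = ("sxo_vs_gsc", "null", "preconditioning_concordance")


def preset_scenario(name: str) -> tuple[NetworkSpec, ScenarioConfig]:
    """Return a preset (network, scenario) pair.

    ``sxo_vs_gsc``
        Two model systems, n = 3 traced replicates each: an explant-like
        group (purine degradation low, GDP-mannose made, pyrimidine
        degradation active, plus 2 tracer-free replicates) versus a
        stem-cell-line-like group (purine degradation high, GDP-mannose not
        detected, pyrimidine degradation off).
    ``null``
        Two identical groups, n = 5 traced replicates each. Group size is
        chosen from permutation granularity: with equal groups every label
        split and its mirror give identical squared-t statistics, so
        exhaustive QEA p-values are even multiples of 1/C(2n, n); 5-vs-5
        (252 splits) puts the largest rejectable p at 6/126 ≈ 0.048,
        making the nominal 5% level achievable.
    ``preconditioning_concordance``
        Two conditions differing only in preconditioning time, identical
        true labeling, independent replicate noise (CV 0.05).
    """
    network = _glutamine_network()
    if name == "sxo_vs_gsc":
        scenario = ScenarioConfig(
            groups=(
                GroupSpec(
                    "SXO_like",
                    n_traced=3,
                    n_unlabeled=2,
                    activity={
                        "purine_degradation": 0.3,
                        "pyrimidine_degradation": 1.0,
                    },
                ),
                GroupSpec(
                    "GSC_like",
                    n_traced=3,
                    activity={
                        "purine_degradation": 1.0,
                        "pyrimidine_degradation": 0.0,
                    },
                    pool_scale={"GDP-mannose": 0.0},
                ),
            ),
            noise_cv=0.10,
        )
    elif name == "null":
        scenario = ScenarioConfig(
            groups=(
                GroupSpec("group_1", n_traced=5),
                GroupSpec("group_2", n_traced=5),
            ),
            noise_cv=0.10,
        )
    elif name == "preconditioning_concordance":
        scenario = ScenarioConfig(
            groups=(
                GroupSpec("precond_24h", n_traced=3, precondition_hours=24.0),
                GroupSpec("precond_120h", n_traced=3, precondition_hours=120.0),
            ),
            noise_cv=0.05,
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {PRESET_NAMES}"
        )
    return network, scenario


def preset_metabolite_sets() -> list[MetaboliteSet]:
    """Metabolite sets matching the preset network's pathways, plus decoys.

    Decoy sets draw only on metabolites whose labeling is identical across
    preset groups, so they are null sets in every preset scenario.
    """
    real = [
        ("purine_degradation", ("adenosine", "inosine", "hypoxanthine")),
        ("purine_synthesis", ("IMP", "AMP", "GMP")),
        ("pyrimidine_synthesis", ("UMP", "uridine")),
        ("pyrimidine_degradation", ("uracil", "dihydrouracil")),
        (
            "amino_acid_synthesis",
            (
                "glutamate",
                "aspartate",
                "alanine",
                "serine",
                "glycine",
                "proline",
                "asparagine",
            ),
        ),
        ("urea_cycle", ("citrulline", "argininosuccinate")),
    ]
    nulls = [
        "glutamine",
        "glutamate",
        "aspartate",
        "alanine",
        "serine",
        "glycine",
        "proline",
        "asparagine",
        "IMP",
        "AMP",
        "GMP",
        "UMP",
        "uridine",
        "citrulline",
        "argininosuccinate",
    ]
    decoys = [
        (f"decoy_{k:02d}", tuple(nulls[(k * 3 + j) % len(nulls)] for j in range(3)))
        for k in range(1, 11)
    ]
    return [
        MetaboliteSet(name, members, "preset")
        for name, members in real + decoys
    ]


def null_scenario_like(
    scenario: ScenarioConfig, noise_cv: float | None = None
) -> ScenarioConfig:
    """Copy a scenario with all groups made identical (global null)."""
    groups = tuple(
        replace(g, activity={}, pool_scale={}) for g in scenario.groups
    )
    return replace(
        scenario,
        groups=groups,
        noise_cv=scenario.noise_cv if noise_cv is None else noise_cv,
    )
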