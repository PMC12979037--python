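"""Natural-isotope-abundance correction of isotopologue distributions.

Measured M+i intensities are contaminated by naturally occurring heavy
isotopes (e.g. 1.07% ¹³C per carbon, 0.364% ¹⁵N per nitrogen). Correction is
posed as the linear model ``measured = M · true`` where ``M`` is a
lower-triangular correction matrix whose column ``j`` is the mass-shift
distribution a molecule carrying exactly ``j`` tracer-derived labels acquires
from natural abundance. The true isotopologue fractions are recovered by
non-negative least squares, which cannot produce negative fractions on noisy
data (unlike a naive matrix inverse).

Two modes are supported:

* ``tracer-only`` — natural abundance of the tracer element over its
  unlabeled tracer atoms only; appropriate for high-resolution instruments
  where isobaric heavy isotopes of other elements are mass-resolved.
* ``all-elements`` — additionally convolves the mass-shift distributions of
  every non-tracer atom in the formula; appropriate for unit-resolution data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import nnls

from ._elements import NATURAL_ABUNDANCE
from .io import IsotopologueVector, MoleculeSpec

__all__ = [
    "NATURAL_ABUNDANCE",
    "AbundanceTable",
    "CorrectionMatrix",
    "CorrectedDistribution",
    "validate_abundance_table",
    "load_abundance_table",
    "build_correction_matrix",
    "correct_vector",
    "correct_dataset",
    "corrected_frame",
    "fractional_enrichment",
    "total_labeling",
]

AbundanceTable = Mapping[str, Sequence[tuple[int, float]]]

MAX_ISOTOPOLOGUES = 64


def validate_abundance_table(table: AbundanceTable) -> None:
    """Check simplex and mass-shift-zero invariants of an abundance table."""
    for element, pairs in table.items():
        shifts = [int(s) for s, _ in pairs]
        probs = np.array([float(p) for _, p in pairs])
        if 0 not in shifts:
            raise ValueError(f"{element}: missing mass-shift-0 isotope")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"{element}: probabilities outside [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{element}: isotope probabilities sum to {probs.sum()!r}, not 1"
            )
        if len(set(shifts)) != len(shifts) or any(s < 0 for s in shifts):
            raise ValueError(f"{element}: invalid mass shifts {shifts}")


def load_abundance_table(path: str | Path) -> dict[str, tuple[tuple[int, float], ...]]:
    """Load an abundance override from YAML (element -> [{shift, probability}])."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    table = {
        element: tuple(
            (int(entry["shift"]), float(entry["probability"])) for entry in entries
        )
        for element, entries in raw.items()
    }
    validate_abundance_table(table)
    return table


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular natural-abundance contamination matrix.

    Entry ``(i, j)`` is the probability that a molecule with ``j``
    tracer-derived labels is measured at nominal shift ``i``. Columns sum to
    1 in tracer-only mode and to <= 1 in all-elements mode (mass shifts
    beyond M+n fall outside the measured window and are dropped).
    """

    metabolite_id: str
    matrix: np.ndarray
    mode: str

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CorrectedDistribution:
    """Natural-abundance-corrected isotopologue fractions for one vector.

    ``fractions`` lie on the simplex when the metabolite was detected
    (``pool_size > 0``); an all-zero measurement yields ``undetected=True``
    and ``fractions=None``.
    """

    metabolite_id: str
    sample_id: str
    fractions: np.ndarray | None
    pool_size: float
    solver_residual: float
    undetected: bool = False


def _shift_dist(element: str, abundances: AbundanceTable, max_shift: int) -> np.ndarray:
    """Dense single-atom mass-shift distribution truncated at ``max_shift``."""
    pairs = abundances[element]
    top = max(int(s) for s, _ in pairs)
    dense = np.zeros(top + 1)
    for shift, prob in pairs:
        dense[int(shift)] = float(prob)
    return dense[: max_shift + 1]


def _convolve_power(dist: np.ndarray, k: int, max_shift: int) -> np.ndarray:
    """k-fold self-convolution of a shift distribution, truncated."""
    out = np.zeros(max_shift + 1)
    out[0] = 1.0
    for _ in range(k):
        out = np.convolve(out, dist)[: max_shift + 1]
    return out


def build_correction_matrix(
    spec: MoleculeSpec,
    abundances: AbundanceTable | None = None,
    mode: str = "tracer-only",
    max_isotopologues: int = MAX_ISOTOPOLOGUES,
) -> CorrectionMatrix:
    """Build the natural-abundance correction matrix for one metabolite.

    In tracer-only mode column ``j`` is the distribution of extra shifts
    contributed by the ``n - j`` unlabeled tracer atoms (a binomial when the
    tracer element has two isotopes). In all-elements mode that distribution
    is convolved with the shift distributions of all non-tracer atoms in the
    formula. Shifts beyond M+n are truncated.
    """
    if mode not in ("tracer-only", "all-elements"):
        raise ValueError(f"unknown correction mode {mode!r}")
    if abundances is None:
        abundances = NATURAL_ABUNDANCE
    else:
        validate_abundance_table(abundances)
    element = spec.tracer_element
    if element not in abundances:
        raise ValueError(
            f"tracer element {element!r} absent from abundance table"
        )
    n = spec.tracer_atom_count
    if n + 1 > max_isotopologues:
        raise ValueError(
            f"{spec.metabolite_id}: {n + 1} isotopologues exceeds the cap of "
            f"{max_isotopologues}"
        )

    tracer_dist = _shift_dist(element, abundances, n)
    base = np.zeros(n + 1)
    base[0] = 1.0
    if mode == "all-elements":
        for elem, count in spec.formula.items():
            extra = int(count) - (n if elem == element else 0)
            if extra > 0:
                base = np.convolve(
                    base, _convolve_power(_shift_dist(elem, abundances, n), extra, n)
                )[: n + 1]

    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = np.convolve(_convolve_power(tracer_dist, n - j, n - j), base)
        col = col[: n + 1 - j]
        matrix[j:, j] = col
    return CorrectionMatrix(spec.metabolite_id, matrix, mode)


def correct_vector(
    raw: IsotopologueVector, matrix: CorrectionMatrix
) -> CorrectedDistribution:
    """Correct one raw isotopologue vector by non-negative least squares.

    Solves ``matrix · x = raw`` for ``x >= 0``; fractions are ``x / Σx``.
    The residual is ``‖matrix·x − raw‖₂ / max(‖raw‖₂, ε)`` and is ~0 for
    noiseless input. An all-zero vector is flagged undetected, not an error.
    """
    y = np.asarray(raw.intensities, dtype=float)
    if y.shape[0] != matrix.size:
        raise ValueError(
            f"{raw.metabolite_id}/{raw.sample_id}: vector length {y.shape[0]} "
            f"does not match correction matrix size {matrix.size}"
        )
    pool = float(y.sum())
    if pool == 0.0:
        return CorrectedDistribution(
            raw.metabolite_id, raw.sample_id, None, 0.0, 0.0, undetected=True
        )
    x, _ = nnls(matrix.matrix, y)
    total = x.sum()
    fractions = x / total if total > 0 else np.zeros_like(x)
    if total == 0:
        # pathological: positive signal explained by nothing; keep M+0
        fractions = np.zeros_like(x)
        fractions[0] = 1.0
    residual = float(
        np.linalg.norm(matrix.matrix @ x - y) / max(np.linalg.norm(y), 1e-300)
    )
    return CorrectedDistribution(
        raw.metabolite_id, raw.sample_id, fractions, pool, residual
    )


# cache of matrices for the default abundance table, keyed by composition
_MATRIX_CACHE: dict[tuple, CorrectionMatrix] = {}


def _cached_matrix(spec: MoleculeSpec, mode: str) -> CorrectionMatrix:
    key = (
        frozenset((e, int(c)) for e, c in spec.formula.items()),
        spec.tracer_atom_count,
        spec.tracer_element,
        mode,
    )
    found = _MATRIX_CACHE.get(key)
    if found is None:
        found = build_correction_matrix(spec, None, mode)
        _MATRIX_CACHE[key] = found
    return CorrectionMatrix(spec.metabolite_id, found.matrix, mode)


def correct_dataset(
    dataset,
    mode: str = "tracer-only",
    abundances: AbundanceTable | None = None,
) -> list[CorrectedDistribution]:
    """Correct every vector in a :class:`~tracescore.io.TracingDataset`."""
    matrices: dict[str, CorrectionMatrix] = {}
    out: list[CorrectedDistribution] = []
    for vec in dataset.iter_vectors():
        matrix = matrices.get(vec.metabolite_id)
        if matrix is None:
            spec = dataset.metabolites[vec.metabolite_id]
            if abundances is None:
                matrix = _cached_matrix(spec, mode)
            else:
                matrix = build_correction_matrix(spec, abundances, mode)
            matrices[vec.metabolite_id] = matrix
        out.append(correct_vector(vec, matrix))
    return out


def corrected_frame(corrected: Iterable[CorrectedDistribution]) -> pd.DataFrame:
    """Long output table: one row per metabolite × sample × isotopologue."""
    rows = []
    for dist in corrected:
        if dist.undetected:
            rows.append(
                (dist.metabolite_id, dist.sample_id, 0, np.nan, 0.0, 0.0, True)
            )
            continue
        for i, f in enumerate(dist.fractions):
            rows.append(
                (
                    dist.metabolite_id,
                    dist.sample_id,
                    i,
                    float(f),
                    dist.pool_size,
                    dist.solver_residual,
                    False,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite_id",
            "sample_id",
            "isotopologue",
            "fraction",
            "pool_size",
            "residual",
            "undetected_flag",
        ],
    )


def fractional_enrichment(dist: CorrectedDistribution, i: int) -> float:
    """Fractional enrichment of the M+i isotopologue (corrected fraction)."""
    if dist.undetected:
        raise ValueError(
            f"{dist.metabolite_id}/{dist.sample_id} is undetected; filter "
            "undetected distributions before querying enrichment"
        )
    if not 0 <= i < len(dist.fractions):
        raise ValueError(
            f"isotopologue index {i} out of range 0..{len(dist.fractions) - 1}"
        )
    return float(dist.fractions[i])


def total_labeling(dist: CorrectedDistribution) -> float:
    """Total fractional enrichment, 1 − FE(M+0).

    The fraction of molecules carrying at least one tracer-derived heavy
    atom; equals the sum of all M+i fractions for i >= 1.
    """
    value = 1.0 - fractional_enrichment(dist, 0)
    return float(min(max(value, 0.0), 1.0))
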