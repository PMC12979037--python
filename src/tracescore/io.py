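"""Tabular input/output for isotope-tracing datasets.

The canonical on-disk representation is three UTF-8 tab-delimited tables:

* ``intensities.tsv`` — long ("tidy") table of raw isotopologue intensities
  with columns ``metabolite_id, sample_id, isotopologue, intensity``;
* ``metabolites.tsv`` — annotations with columns
  ``metabolite_id, formula, tracer_atom_count`` (optional ``tracer_element``);
* ``samples.tsv`` — sample metadata with columns
  ``sample_id, model_system, tracer_condition, precondition_hours, replicate``.

Metabolite sets are read from GMT files (one set per line:
name, description, member ids, tab-separated).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from ._elements import RECOGNIZED_ELEMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "FormulaError",
    "ValidationError",
    "MoleculeSpec",
    "SampleMeta",
    "IsotopologueVector",
    "MetaboliteSet",
    "TracingDataset",
    "parse_formula",
    "write_formula",
    "read_tracing_dataset",
    "read_wide_intensities",
    "read_metabolite_sets",
    "write_metabolite_sets",
]


class FormulaError(ValueError):
    """A chemical formula string could not be parsed."""


class ValidationError(ValueError):
    """A dataset violated the three-table data model."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula_text: str) -> dict[str, int]:
    """Parse a Hill-notation-like formula string into an element-count map.

    Each token is an element symbol (capital letter, optional lowercase
    letter) followed by an optional positive integer count; an absent count
    means 1. Example: ``"C5H10N2O3"`` -> ``{"C": 5, "H": 10, "N": 2, "O": 3}``.
    """
    if not isinstance(formula_text, str) or not formula_text.strip():
        raise FormulaError("empty formula string")
    text = formula_text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(
                f"cannot parse formula {formula_text!r}: unexpected token at "
                f"{text[pos:]!r}"
            )
        symbol, digits = m.groups()
        if symbol not in RECOGNIZED_ELEMENTS:
            raise FormulaError(
                f"cannot parse formula {formula_text!r}: unknown element "
                f"symbol {symbol!r}"
            )
        if digits == "":
            count = 1
        else:
            count = int(digits)
            if count <= 0:
                raise FormulaError(
                    f"cannot parse formula {formula_text!r}: non-positive "
                    f"count for {symbol!r}"
                )
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return counts


def write_formula(counts: Mapping[str, int]) -> str:
    """Write an element-count map as a canonical Hill-order formula string.

    Carbon first, then hydrogen, then remaining elements alphabetically;
    counts of 1 are omitted. Inverse of :func:`parse_formula`.
    """
    if not counts:
        raise FormulaError("empty element map")
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    parts = []
    for element in order:
        n = int(counts[element])
        if n <= 0:
            raise FormulaError(f"non-positive count for element {element!r}")
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


@dataclass(frozen=True)
class MoleculeSpec:
    """Identity, elemental composition and tracer-atom count of a metabolite.

    ``tracer_atom_count`` is the number of atoms of the tracer element that
    can carry label; it sets the maximum isotopologue index M+n.
    """

    metabolite_id: str
    formula: Mapping[str, int]
    tracer_atom_count: int
    tracer_element: str = "N"

    def __post_init__(self) -> None:
        for element, count in self.formula.items():
            if element not in RECOGNIZED_ELEMENTS:
                raise ValidationError(
                    f"{self.metabolite_id}: unrecognized element {element!r}"
                )
            if int(count) < 0:
                raise ValidationError(
                    f"{self.metabolite_id}: negative count for {element!r}"
                )
        if self.tracer_atom_count < 0:
            raise ValidationError(
                f"{self.metabolite_id}: tracer_atom_count must be >= 0"
            )
        if self.tracer_atom_count > self.formula.get(self.tracer_element, 0):
            raise ValidationError(
                f"{self.metabolite_id}: tracer_atom_count "
                f"{self.tracer_atom_count} exceeds {self.tracer_element} "
                f"count in formula {write_formula(self.formula)}"
            )

    @property
    def n_isotopologues(self) -> int:
        return self.tracer_atom_count + 1


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample (one replicate of one condition)."""

    sample_id: str
    model_system: str
    tracer_condition: str
    precondition_hours: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.tracer_condition not in ("traced", "unlabeled"):
            raise ValidationError(
                f"{self.sample_id}: tracer_condition must be 'traced' or "
                f"'unlabeled', got {self.tracer_condition!r}"
            )
        if self.precondition_hours < 0:
            raise ValidationError(
                f"{self.sample_id}: precondition_hours must be >= 0"
            )
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")


@dataclass
class IsotopologueVector:
    """Raw measured intensities M+0..M+n for one metabolite in one sample."""

    metabolite_id: str
    sample_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValidationError("intensities must be one-dimensional")
        if np.any(self.intensities < 0):
            raise ValidationError(
                f"{self.metabolite_id}/{self.sample_id}: negative intensity"
            )

    @property
    def pool_size(self) -> float:
        return float(self.intensities.sum())

    @property
    def undetected(self) -> bool:
        return bool(self.pool_size == 0.0)


@dataclass(frozen=True)
class MetaboliteSet:
    """A named set of metabolites (one GMT line)."""

    set_name: str
    member_ids: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValidationError(f"{self.set_name}: empty metabolite set")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError(f"{self.set_name}: duplicate member ids")


@dataclass
class TracingDataset:
    """Validated in-memory form of the three-table data model.

    Holds one :class:`IsotopologueVector` for every (metabolite, sample)
    pair — missing rows are zero-filled so that undetected metabolites flow
    through the pipeline rather than crashing it.
    """

    metabolites: dict[str, MoleculeSpec]
    samples: dict[str, SampleMeta]
    vectors: dict[tuple[str, str], IsotopologueVector] = field(repr=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        intensities: pd.DataFrame,
        metabolites: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> "TracingDataset":
        """Build and validate a dataset from the three canonical tables."""
        req_int = {"metabolite_id", "sample_id", "isotopologue", "intensity"}
        req_met = {"metabolite_id", "formula", "tracer_atom_count"}
        req_sam = {
            "sample_id",
            "model_system",
            "tracer_condition",
            "precondition_hours",
            "replicate",
        }
        for frame, req, name in (
            (intensities, req_int, "intensities"),
            (metabolites, req_met, "metabolites"),
            (samples, req_sam, "samples"),
        ):
            missing = req - set(frame.columns)
            if missing:
                raise ValidationError(
                    f"{name} table missing columns: {sorted(missing)}"
                )

        specs: dict[str, MoleculeSpec] = {}
        for row in metabolites.itertuples(index=False):
            mid = str(row.metabolite_id).strip()
            if mid in specs:
                raise ValidationError(f"duplicate metabolite annotation: {mid}")
            specs[mid] = MoleculeSpec(
                metabolite_id=mid,
                formula=parse_formula(str(row.formula)),
                tracer_atom_count=int(row.tracer_atom_count),
                tracer_element=str(getattr(row, "tracer_element", "N")),
            )

        metas: dict[str, SampleMeta] = {}
        for row in samples.itertuples(index=False):
            sid = str(row.sample_id).strip()
            if sid in metas:
                raise ValidationError(f"duplicate sample_id: {sid}")
            metas[sid] = SampleMeta(
                sample_id=sid,
                model_system=str(row.model_system).strip(),
                tracer_condition=str(row.tracer_condition).strip(),
                precondition_hours=float(row.precondition_hours),
                replicate=int(row.replicate),
            )

        ints = intensities.copy()
        ints["metabolite_id"] = ints["metabolite_id"].astype(str).str.strip()
        ints["sample_id"] = ints["sample_id"].astype(str).str.strip()

        unknown_mets = sorted(set(ints["metabolite_id"]) - set(specs))
        if unknown_mets:
            raise ValidationError(
                f"intensity rows reference unannotated metabolites: "
                f"{unknown_mets}"
            )
        unknown_samples = sorted(set(ints["sample_id"]) - set(metas))
        if unknown_samples:
            raise ValidationError(
                f"intensity rows reference unknown samples: {unknown_samples}"
            )
        if (ints["intensity"] < 0).any():
            bad = ints.loc[ints["intensity"] < 0]
            raise ValidationError(
                "negative intensities for: "
                + ", ".join(
                    f"{r.metabolite_id}/{r.sample_id}/M+{int(r.isotopologue)}"
                    for r in bad.head(10).itertuples(index=False)
                )
            )

        observed_mets = list(dict.fromkeys(ints["metabolite_id"]))
        vectors: dict[tuple[str, str], IsotopologueVector] = {}
        grouped = {
            key: grp for key, grp in ints.groupby(["metabolite_id", "sample_id"])
        }
        n_zero_filled = 0
        for mid in observed_mets:
            spec = specs[mid]
            n = spec.tracer_atom_count
            for sid in metas:
                key = (mid, sid)
                arr = np.zeros(n + 1, dtype=float)
                grp = grouped.get(key)
                if grp is None:
                    n_zero_filled += n + 1
                    logger.warning(
                        "no intensity rows for %s in sample %s; zero-filled",
                        mid,
                        sid,
                    )
                else:
                    idx = grp["isotopologue"].to_numpy(dtype=int)
                    if (idx < 0).any() or (idx > n).any():
                        raise ValidationError(
                            f"{mid}/{sid}: isotopologue index out of range "
                            f"0..{n}: {sorted(set(idx) - set(range(n + 1)))}"
                        )
                    if len(set(idx)) != len(idx):
                        raise ValidationError(
                            f"{mid}/{sid}: duplicate isotopologue rows"
                        )
                    arr[idx] = grp["intensity"].to_numpy(dtype=float)
                    missing = (n + 1) - len(idx)
                    if missing:
                        n_zero_filled += missing
                        logger.warning(
                            "%s/%s: %d missing isotopologue rows zero-filled",
                            mid,
                            sid,
                            missing,
                        )
                vectors[key] = IsotopologueVector(mid, sid, arr)
        if n_zero_filled:
            logger.info("zero-filled %d missing isotopologue entries", n_zero_filled)
        return cls(metabolites=specs, samples=metas, vectors=vectors)

    # -- iteration / access ----------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return sorted({m for m, _ in self.vectors})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def vector(self, metabolite_id: str, sample_id: str) -> IsotopologueVector:
        return self.vectors[(metabolite_id, sample_id)]

    def iter_vectors(self) -> Iterator[IsotopologueVector]:
        return iter(self.vectors.values())

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "model_system": s.model_system,
                    "tracer_condition": s.tracer_condition,
                    "precondition_hours": s.precondition_hours,
                    "replicate": s.replicate,
                }
                for s in self.samples.values()
            ]
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Return the three canonical tables (long intensities first)."""
        rows = []
        for vec in self.vectors.values():
            for i, value in enumerate(vec.intensities):
                rows.append(
                    (vec.metabolite_id, vec.sample_id, i, float(value))
                )
        intensities = pd.DataFrame(
            rows,
            columns=["metabolite_id", "sample_id", "isotopologue", "intensity"],
        )
        mets = pd.DataFrame(
            [
                {
                    "metabolite_id": s.metabolite_id,
                    "formula": write_formula(s.formula),
                    "tracer_atom_count": s.tracer_atom_count,
                    "tracer_element": s.tracer_element,
                }
                for s in self.metabolites.values()
            ]
        )
        return intensities, mets, self.samples_frame()

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three tables to ``out_dir`` and return their paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        intensities, mets, samples = self.to_frames()
        paths = {
            "intensities": out / "intensities.tsv",
            "metabolites": out / "metabolites.tsv",
            "samples": out / "samples.tsv",
        }
        intensities.to_csv(paths["intensities"], sep="\t", index=False)
        mets.to_csv(paths["metabolites"], sep="\t", index=False)
        samples.to_csv(paths["samples"], sep="\t", index=False)
        return paths


def read_wide_intensities(path: str | Path) -> pd.DataFrame:
    """Read a wide intensity table (columns ``M+0, M+1, ...``) as long format.

    Convenience reader; the long format is canonical. Requires columns
    ``metabolite_id`` and ``sample_id`` plus one ``M+i`` column per
    isotopologue (missing cells treated as 0).
    """
    wide = pd.read_csv(path, sep="\t")
    iso_cols = [c for c in wide.columns if re.fullmatch(r"M\+\d+", c)]
    if not iso_cols:
        raise ValidationError(f"{path}: no M+i columns found")
    long = wide.melt(
        id_vars=["metabolite_id", "sample_id"],
        value_vars=iso_cols,
        var_name="isotopologue",
        value_name="intensity",
    )
    long["isotopologue"] = long["isotopologue"].str.removeprefix("M+").astype(int)
    long["intensity"] = long["intensity"].fillna(0.0)
    return long


def read_tracing_dataset(
    intensity_path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
    wide: bool = False,
) -> TracingDataset:
    """Read and validate the three-table dataset from disk."""
    if wide:
        intensities = read_wide_intensities(intensity_path)
    else:
        intensities = pd.read_csv(intensity_path, sep="\t")
    metabolites = pd.read_csv(annotation_path, sep="\t")
    samples = pd.read_csv(metadata_path, sep="\t")
    return TracingDataset.from_frames(intensities, metabolites, samples)


def read_metabolite_sets(path: str | Path) -> list[MetaboliteSet]:
    """Read metabolite sets from a GMT file (name, description, members...)."""
    sets: list[MetaboliteSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, description, *members = fields
            members = [m.strip() for m in members if m.strip()]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "%s:%d: duplicate member ids in set %r deduplicated",
                    path,
                    lineno,
                    name,
                )
            if not deduped:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets.append(MetaboliteSet(name, tuple(deduped), description))
    return sets


def write_metabolite_sets(sets: Iterable[MetaboliteSet], path: str | Path) -> None:
    """Write metabolite sets as a GMT file."""
    with open(path, "w", encoding="utf-8") as handle:
        for s in sets:
            handle.write(
                "\t".join([s.set_name, s.description or "-", *s.member_ids]) + "\n"
            )
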