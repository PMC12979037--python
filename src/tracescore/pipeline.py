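"""End-to-end orchestration: correct → score → diff → QEA, with manifest.

A run is a pure function of (inputs, config, seed): identical re-runs write
bit-identical outputs, recorded as SHA-256 checksums in ``manifest.json``.
On a stage failure, whatever partial outputs exist are moved to a
``quarantine/`` subdirectory and the error names the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correction import load_abundance_table
from .io import read_metabolite_sets, read_tracing_dataset
from .model import IsotopeTracingModel
from .scoring import FilterPolicy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "qc_report"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    intensities: str
    metabolites: str
    samples: str
    sets: str | None = None
    abundances: str | None = None
    correction_mode: str = "tracer-only"
    reference_metabolite: str = "glutamate"
    min_total_labeling: float = 0.0
    min_pool_size: float = 0.01
    pool_size_mode: str = "fraction-of-sample-median"
    group_a: str | None = None
    group_b: str | None = None
    p_threshold: float = 0.05
    fc_threshold: float = 1.25
    test: str = "welch"
    n_permutations: int = 9999
    seed: int = 0
    out_dir: str = "tracescore_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        fields = {k: v for k, v in raw.items() if k in known}
        fields["extra"] = {k: v for k, v in raw.items() if k not in known}
        fields.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**fields)

    def validate(self) -> None:
        for name in ("intensities", "metabolites", "samples"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} table not found: {path}")
        for name in ("sets", "abundances"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def qc_report(results) -> pd.DataFrame:
    """QC table for fitted results (see ``IsotopeTracingResults.qc``)."""
    return results.qc()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Writes ``corrected.tsv``, ``scores.tsv``, ``qc.tsv`` and, when two
    groups are configured, ``volcano.tsv`` (and ``enrichment.tsv`` when a
    sets file is given), plus ``manifest.json``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    counts: dict[str, int] = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written[name] = path
        counts[f"{name}_rows"] = len(frame)

    try:
        stage = "read"
        dataset = read_tracing_dataset(
            config.intensities, config.metabolites, config.samples
        )
        counts["metabolites"] = len(dataset.metabolite_ids)
        counts["samples"] = len(dataset.samples)

        abundances = (
            load_abundance_table(config.abundances) if config.abundances else None
        )
        policy = FilterPolicy(
            min_total_labeling=config.min_total_labeling,
            min_pool_size=config.min_pool_size,
            pool_size_mode=config.pool_size_mode,
        )
        model = IsotopeTracingModel(
            dataset,
            correction_mode=config.correction_mode,
            abundances=abundances,
            filter_policy=policy,
            reference_metabolite=config.reference_metabolite,
        )

        stage = "correct"
        results = model.fit()
        _write("corrected", results.corrected_frame)

        stage = "score"
        _write("scores", results.scores)

        stage = "qc"
        _write("qc", results.qc())

        if config.group_a and config.group_b:
            stage = "diff"
            volcano = results.compare_groups(
                config.group_a,
                config.group_b,
                p_threshold=config.p_threshold,
                fc_threshold=config.fc_threshold,
                test=config.test,
            )
            _write("volcano", volcano)
            counts["volcano_tested"] = int((volcano["status"] == "tested").sum())
            counts["volcano_exclusive"] = int(
                volcano["status"].str.startswith("exclusive").sum()
            )
            counts["volcano_filtered"] = int((volcano["status"] == "filtered").sum())

            if config.sets:
                stage = "qea"
                sets = read_metabolite_sets(config.sets)
                enrichment = results.set_enrichment(
                    sets,
                    config.group_a,
                    config.group_b,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                )
                _write("enrichment", enrichment)
                counts["enrichment_untestable"] = int(
                    (enrichment["status"] == "untestable").sum()
                )
    except Exception as err:
        quarantine = out_dir / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for name, path in written.items():
            path.rename(quarantine / path.name)
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err}; partial outputs moved "
            f"to {quarantine}"
        ) from err

    stage = "manifest"
    manifest = {
        "tracescore_version": __version__,
        "fold_change_direction": f"{config.group_b} relative to {config.group_a}",
        "config": asdict(config),
        "counts": counts,
        "outputs": {name: str(path) for name, path in written.items()},
        "checksums": {name: _sha256(path) for name, path in written.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d outputs in %s", len(written), out_dir)
    return manifest
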