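"""End-to-end pipeline orchestration with config, logging and provenance.

Stages run in order: (optional) simulate -> read -> singleton filter ->
annotate -> diversity/publicity statistics -> association analyses.  A run
writes every output table plus a manifest (content hashes), a
machine-readable exclusion-count JSON, and the resolved config, so reruns
with the same config are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_clonotypes
from .association import FEATURES, compare_subsets, enrichment_by_frequency_class, length_distribution_by_class
from .germline import load_reference
from .io import filter_singletons, read_repertoire, write_repertoire, write_table
from .simulate import SimulationConfig, SubsetSpec, simulate_cohort
from .statistics import (
    StatisticsError,
    collapse_and_score_publicity,
    diversity_metrics,
    replicate_concordant_nucleotypes,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class PipelineConfig:
    """Fully serializable run configuration (written next to the outputs)."""

    outdir: str = "results/run"
    seed: int = 0
    simulate: bool = True  # when False, repertoire/metadata paths must exist
    repertoire_path: str | None = None
    metadata_path: str | None = None
    count_column: str = "duplicate_count"
    min_d_match: int = 3
    allow_unequal_cells: bool = False
    alpha: float = 0.05
    compare_metrics: tuple[str, ...] = ("shannon", "richness", "d75")
    simulation: dict = field(default_factory=dict)  # overrides for SimulationConfig

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("config_hash", None)
        if "compare_metrics" in raw:
            raw["compare_metrics"] = tuple(raw["compare_metrics"])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        # identifies the scientific configuration; output location excluded
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    overrides = dict(config.simulation)
    if "subsets" in overrides:
        overrides["subsets"] = tuple(SubsetSpec(**s) for s in overrides["subsets"])
    overrides.setdefault("seed", config.seed)
    return SimulationConfig(**overrides)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the output manifest (file -> sha256)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"cdr3delta {__version__} config={config.config_hash}"
    exclusions = {"singletons_removed": 0, "nonproductive": 0, "short_junctions": 0, "unknown_j": 0}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate" if config.simulate else "read")
        if config.simulate:
            samples, truth = simulate_cohort(_simulation_config(config))
            write_repertoire(
                samples, outdir / "repertoire.tsv", outdir / "metadata.tsv", header_comment=header
            )
            write_table(truth, outdir / "ground_truth.tsv", header_comment=header)
        else:
            if not config.repertoire_path or not config.metadata_path:
                raise PipelineError("I/O stage: repertoire_path and metadata_path are required")
            samples = read_repertoire(
                config.repertoire_path, config.metadata_path, count_column=config.count_column
            )
    except (OSError, ValueError) as exc:
        raise PipelineError(f"I/O stage failed: {exc}") from exc

    stage("filter")
    before = sum(len(s) for s in samples)
    samples = [filter_singletons(s) for s in samples]
    samples = [s for s in samples if len(s)]
    exclusions["singletons_removed"] = before - sum(len(s) for s in samples)

    stage("annotate")
    try:
        reference = load_reference()
        annotated = annotate_clonotypes(samples, reference, min_d_match=config.min_d_match)
    except ValueError as exc:
        raise PipelineError(f"annotation stage failed: {exc}") from exc
    exclusions["nonproductive"] = int((~annotated["productive"].astype(bool)).sum())
    exclusions["short_junctions"] = int(
        (annotated["productive"].astype(bool) & annotated["aa5"].isna()).sum()
    )
    exclusions["unknown_j"] = int(
        (annotated["productive"].astype(bool) & annotated["j_region"].isna()).sum()
    )
    write_table(
        annotated,
        outdir / "annotations.tsv",
        sort_by=["sample_id", "junction", "v_call", "j_call"],
        header_comment=header,
    )

    stage("statistics")
    try:
        div = pd.DataFrame([dataclasses.asdict(diversity_metrics(s)) for s in samples])
        write_table(div, outdir / "diversity.tsv", sort_by=["sample_id"], header_comment=header)
        by_donor: dict[str, list] = {}
        for s in samples:
            by_donor.setdefault(s.donor_id, []).append(s)
        concordant = {}
        for donor, donor_samples in by_donor.items():
            if len(donor_samples) >= 2:
                concordant[donor] = replicate_concordant_nucleotypes(donor_samples)
            else:
                log.warning("donor %s has a single sample; skipped in publicity", donor)
        publicity = (
            collapse_and_score_publicity(concordant) if len(concordant) >= 2 else pd.DataFrame()
        )
        write_table(
            publicity,
            outdir / "publicity.tsv",
            sort_by=["junction_aa"] if len(publicity) else None,
            header_comment=header,
        )
    except StatisticsError as exc:
        raise PipelineError(f"statistics stage failed: {exc}") from exc

    stage("associations")
    try:
        if len(publicity):
            annotated = annotated.merge(
                publicity[["junction_aa", "is_public"]], on="junction_aa", how="left"
            )
            col = annotated["is_public"]
            annotated["is_public"] = col.where(col.notna(), False).astype(bool)
        features = [f for f in FEATURES if f != "public" or "is_public" in annotated.columns]
        enrich = pd.concat(
            [enrichment_by_frequency_class(annotated, f) for f in features], ignore_index=True
        )
        write_table(
            enrich,
            outdir / "enrichment.tsv",
            sort_by=["feature", "level", "donor_id", "subset_label", "frequency_class", "sample_id"],
            header_comment=header,
        )
        lengths = length_distribution_by_class(annotated, restrict_to="J1")
        write_table(
            lengths,
            outdir / "length_distribution_J1.tsv",
            sort_by=["frequency_class", "cdr3_length"],
            header_comment=header,
        )
        subsets = sorted(annotated["subset_label"].unique())
        comparisons = []
        if len(subsets) == 2:
            a, b = subsets
            for metric in config.compare_metrics:
                res = compare_subsets(annotated, a, b, metric)
                comparisons.append({"metric": metric, **dataclasses.asdict(res)})
        write_table(
            pd.DataFrame(comparisons),
            outdir / "comparisons.tsv",
            sort_by=["metric"] if comparisons else None,
            header_comment=header,
        )
    except StatisticsError as exc:
        raise PipelineError(f"association stage failed: {exc}") from exc

    stage("provenance")
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "exclusions.json", "w", encoding="utf-8") as fh:
        json.dump(exclusions, fh, indent=2, sort_keys=True)
    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
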