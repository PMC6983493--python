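"""End-to-end orchestration: ingest -> meta-cluster -> frequencies -> summary.

Chains the library stages on files, with a validated configuration,
per-stage record counts reconciled in a run log, and deterministic
outputs (same inputs and seed give byte-identical files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io_formats, metacluster, popstats, synth
from .metacluster import ClusteringGrid, ClusterPolicy
from .models import RobustSV, Technology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerInput:
    caller: str
    technology: str
    path: str


@dataclass
class PipelineConfig:
    """Inputs and constants for one end-to-end run."""

    genome_length: int
    manifest: list[CallerInput]
    coverage: str
    annotation: str | None = None
    mode: str = "cross_technology"
    grid: ClusteringGrid = field(default_factory=ClusteringGrid)
    policy: ClusterPolicy | None = None
    robust_fraction: float = 0.0498
    contig: str = "genome"

    def __post_init__(self) -> None:
        if self.policy is None:
            self.policy = ClusterPolicy(support_mode=self.mode)


def validate_config(config: PipelineConfig) -> None:
    """Fail before any computation when a referenced input is missing."""
    if config.genome_length <= 0:
        raise ValueError("config field 'genome_length' must be positive")
    if not config.manifest:
        raise ValueError("config field 'manifest' is empty")
    for entry in config.manifest:
        if not Path(entry.path).exists():
            raise ValueError(
                f"config field 'manifest': file not found for caller "
                f"{entry.caller}: {entry.path}"
            )
    if not Path(config.coverage).exists():
        raise ValueError(f"config field 'coverage': file not found: {config.coverage}")
    if config.annotation is not None and not Path(config.annotation).exists():
        raise ValueError(
            f"config field 'annotation': file not found: {config.annotation}"
        )


def _frequency_table(svs: Sequence[RobustSV], freqs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sv_id": [fe.sv_id for fe in freqs],
            "sv_type": [sv.sv_type.value for sv in svs],
            "start": [sv.consensus_start for sv in svs],
            "end": [sv.consensus_end for sv in svs],
            "length": [sv.consensus_length for sv in svs],
            "support": [fe.sv_support for fe in freqs],
            "ref_coverage": [round(fe.ref_coverage, 2) for fe in freqs],
            "frequency": [round(fe.f, 8) for fe in freqs],
            "callers": [",".join(sorted(sv.callers)) for sv in svs],
            "technologies": [
                ",".join(sorted(t.value for t in sv.technologies)) for sv in svs
            ],
        }
    )


def run_end_to_end(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write every output table.

    Returns a dictionary with the output paths and the per-stage record
    counts (also written to ``run_log.json``).
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": []}

    def stage(name: str, n_in: int, n_out: int) -> None:
        log["stages"].append(
            {"stage": name, "records_in": n_in, "records_out": n_out,
             "filtered": n_in - n_out}
        )

    all_calls = []
    skip_report: dict[str, dict[str, int]] = {}
    for entry in config.manifest:
        parsed = io_formats.read_caller_calls(
            entry.path, entry.caller, entry.technology, config.genome_length
        )
        all_calls.extend(parsed.calls)
        skip_report[entry.caller] = parsed.skipped
    log["skipped_records"] = skip_report

    coverage = io_formats.read_coverage(config.coverage, config.genome_length)
    annotation = (
        io_formats.read_annotation(config.annotation, config.genome_length)
        if config.annotation
        else None
    )

    harmonized = metacluster.harmonize(all_calls, config.policy)
    stage("harmonize", len(all_calls), len(harmonized))

    union = metacluster.run_grid(harmonized, config.grid, config.policy)
    stage("grid_union", len(harmonized), len(union))

    deduped = metacluster.dedupe(union)
    stage("dedupe", len(union), len(deduped))

    final = metacluster.circular_filter(
        deduped, config.genome_length, config.policy
    )
    stage("circular_filter", len(deduped), len(final))

    freqs = [popstats.sv_frequency(sv, coverage) for sv in final]
    for sv, fe in zip(final, freqs):
        sv.frequency = fe.f

    robust = metacluster.select_robust_subset(final, config.robust_fraction)
    stage("robust_subset", len(final), len(robust))

    summary = popstats.summarize(final, freqs, annotation)

    paths = {
        "merged_vcf": outdir / "merged.vcf",
        "frequencies": outdir / "frequencies.tsv",
        "summary": outdir / "summary.tsv",
        "robust_subset": outdir / "robust_subset.tsv",
        "run_log": outdir / "run_log.json",
    }
    io_formats.write_sv_vcf(
        final, paths["merged_vcf"], config.genome_length, config.contig
    )
    freq_table = _frequency_table(final, freqs)
    freq_table.to_csv(paths["frequencies"], sep="\t", index=False)
    summary.to_frame().to_csv(paths["summary"], sep="\t", index=False)
    robust_ids = {id(sv) for sv in robust}
    freq_table[[id(sv) in robust_ids for sv in final]].to_csv(
        paths["robust_subset"], sep="\t", index=False
    )
    if summary.feature_burden:
        log["feature_burden_pct"] = {
            k: round(100 * v, 4) for k, v in summary.feature_burden.items()
        }
    with open(paths["run_log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "log": log,
        "n_final_svs": len(final),
        "n_robust": len(robust),
        "summary": summary,
        "final_svs": final,
        "frequencies": freqs,
    }


def simulate_inputs(
    outdir: str | Path,
    genome_length: int = 50_000,
    depth: int = 2000,
    seed: int = 42,
    sv_counts: dict | None = None,
    chimera_rate: float = 0.0,
) -> tuple[PipelineConfig, synth.TruthSet]:
    """Generate a synthetic dataset on disk and a config pointing at it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequence, annotation = synth.make_genome(genome_length, seed=seed)
    truth = synth.plant_svs(
        annotation, counts=sv_counts, depth=depth, seed=seed + 1,
        sequence=sequence,
    )
    profiles = synth.default_profiles()
    calls, coverage = synth.simulate_caller_outputs(
        truth, profiles, depth=depth, seed=seed + 2
    )
    if chimera_rate > 0:
        calls, chimera_manifest = synth.inject_chimeras(
            calls, profiles, genome_length, rate=chimera_rate, seed=seed + 3
        )
    else:
        chimera_manifest = []

    manifest: list[CallerInput] = []
    for profile in profiles:
        path = outdir / f"{profile.name}.vcf"
        io_formats.write_sv_vcf(
            calls[profile.name], path, genome_length, contig="genome"
        )
        manifest.append(
            CallerInput(profile.name, profile.technology.value, str(path))
        )
    cov_path = io_formats.write_coverage(coverage, outdir / "coverage.txt")
    ann_path = io_formats.write_annotation(annotation, outdir / "annotation.gff3")
    io_formats.write_fasta(sequence, outdir / "genome.fasta")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "genome_length": genome_length,
                "depth": depth,
                "planted_svs": [
                    {
                        "sv_type": sv.sv_type.value,
                        "start": sv.start,
                        "end": sv.end,
                        "length": sv.length,
                        "frequency": sv.frequency,
                    }
                    for sv in truth.planted_svs
                ],
                "chimera_artifacts": chimera_manifest,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    config = PipelineConfig(
        genome_length=genome_length,
        manifest=manifest,
        coverage=str(cov_path),
        annotation=str(ann_path),
    )
    return config, truth
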