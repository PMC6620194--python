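"""End-to-end wiring: simulate -> extract -> barcodes -> chimera.

`analyze_sample` is the analysis half (tally to SampleReport); `run_end_to_end`
drives a full simulated experiment in memory/on disk; `run_pipeline` executes a
RunConfig with staged logging for the command-line interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from mprachim import barcodes as bc_mod
from mprachim import chimera as chim_mod
from mprachim.design import LibraryDesign, PlasmidLibrary, random_library
from mprachim.extract import TallyResult, Tolerances, parse_fastq, tally_pairs
from mprachim.simulate import (
    ErrorModel,
    ProtocolParams,
    emit_fastq,
    params_sidecar,
    run_protocol,
)

logger = logging.getLogger("mprachim")


@dataclass(frozen=True)
class AnalysisThresholds:
    """Downstream analysis knobs: collapse distance, read support, ROI error
    distance and the sample-percent denominator."""

    max_subs: int = 2
    min_reads: int = 2
    roi_error_dist: int = 1
    denominator: str = "defined-roi"
    ambiguous: str = "nearest"


@dataclass
class SampleAnalysis:
    """Everything computed for one sample."""

    report: chim_mod.SampleReport
    bc_reports: dict[str, chim_mod.BCReport]
    clusters: list[bc_mod.BarcodeCluster]
    genuine_bcs: set[str]


def analyze_sample(
    tally: dict[str, dict[str, int]],
    condition: str,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> SampleAnalysis:
    """Genuine-BC calling and chimera classification for one sample tally.

    ``tally`` maps observed BC -> (ROI -> read count), as produced by
    :func:`mprachim.extract.tally_pairs` for one sample.
    """
    bc_counts = {bc: sum(rois.values()) for bc, rois in tally.items()}
    clusters = bc_mod.collapse_barcodes(
        bc_counts, max_subs=thresholds.max_subs, ambiguous=thresholds.ambiguous
    )
    kept = bc_mod.filter_clusters(clusters, min_reads=thresholds.min_reads)
    genuine = {c.genuine_bc for c in kept}
    roi_by_bc = chim_mod.cluster_roi_counts(kept, tally)
    reports, undefined_reads = chim_mod.bc_reports(
        roi_by_bc, error_dist=thresholds.roi_error_dist
    )
    sample_report = chim_mod.sample_summary(
        reports,
        condition,
        undefined_reads=undefined_reads,
        denominator=thresholds.denominator,
    )
    return SampleAnalysis(
        sample_report, {r.genuine_bc: r for r in reports}, kept, genuine
    )


def run_end_to_end(
    library: PlasmidLibrary,
    params: ProtocolParams,
    error_model: ErrorModel,
    n_reads: int,
    seed: int,
    workdir: str | Path,
    sample: str | None = None,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    condition: str | None = None,
):
    """Simulate one sample, write FASTQ + truth, and analyze it back.

    Returns ``(analysis, truth, pool)``: the :class:`SampleAnalysis`, the truth
    table written next to the FASTQ, and the simulated species pool.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if sample is None:
        sample = next(iter(library.design.index_table))
    if condition is None:
        condition = f"{params.mode}_p{params.switch_prob:g}"
    rng = np.random.default_rng(seed)
    pool = run_protocol(library, params, rng)
    fastq = workdir / "reads.fastq"
    truth = emit_fastq(
        pool,
        sample,
        n_reads,
        error_model,
        rng,
        fastq,
        truth_path=workdir / "truth.tsv",
        sidecar=params_sidecar(params, error_model, seed),
    )
    result = tally_pairs(parse_fastq(fastq, library.design))
    analysis = analyze_sample(result.tallies.get(sample, {}), condition, thresholds)
    return analysis, truth, pool


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    outdir: str = "mprachim_run"
    seed: int = 0
    n_clones: int = 1000
    n_reads: int = 100_000
    sample: str | None = None
    design: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    sub_rate: float = 1e-3
    thresholds: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run simulate -> extract -> barcodes -> chimera per ``config``.

    All artifacts land under ``config.outdir``; every table carries the config
    hash in its header line.  Reruns with the same config are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    design = LibraryDesign(**config.design)
    thresholds = AnalysisThresholds(**config.thresholds)
    params = ProtocolParams(**config.protocol)
    error_model = ErrorModel(sub_rate=config.sub_rate)

    stage = "simulate"
    try:
        logger.info("[%s] library of %d clones (seed %d)", stage, config.n_clones, config.seed)
        library = random_library(config.n_clones, design, seed=config.seed)
        library.to_tsv(outdir / "library.tsv")
        analysis, truth, pool = run_end_to_end(
            library,
            params,
            error_model,
            config.n_reads,
            config.seed,
            outdir,
            sample=config.sample,
            thresholds=thresholds,
        )
        stage = "report"
        report = analysis.report
        summary = {
            "config_hash": chash,
            "condition": report.condition,
            "n_genuine_bcs": report.n_genuine_bcs,
            "total_read_count": report.total_read_count,
            "chimeric_read_count": report.chimeric_read_count,
            "chimeric_read_percent": round(report.chimeric_read_percent, 3),
            "pool_chimeric_fraction": pool.chimeric_fraction,
            "truth_chimeric_fraction": float(truth.chimeric.mean()),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        with open(outdir / "bc_reports.tsv", "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            fh.write("genuine_bc\tgenuine_roi\tn_genuine\tn_error\tn_chimeric\tproportion\n")
            for r in sorted(analysis.bc_reports.values(), key=lambda r: r.genuine_bc):
                fh.write(
                    f"{r.genuine_bc}\t{r.genuine_roi}\t{r.n_genuine}\t{r.n_error}"
                    f"\t{r.n_chimeric}\t{r.chimera_proportion:.6f}\n"
                )
        logger.info(
            "[%s] %.3f%% chimeric reads over %d genuine BCs",
            stage,
            report.chimeric_read_percent,
            report.n_genuine_bcs,
        )
        return summary
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


DEMO_CONFIGS: dict[str, dict] = {
    # Two clones in one pot, one long round: detectable chimeras.
    "two-plasmid": {
        "n_clones": 2,
        "n_reads": 50_000,
        "protocol": {
            "mode": "conventional",
            "template_molecules": 20_000,
            "cycles_round1": 25,
            "cycles_round2": 1,
            "carryover_fraction": 0.01,
            "switch_prob": 1e-3,
        },
    },
    # Diverse library, two-round emulsion protocol at low occupancy.
    "library-71-epcr": {
        "n_clones": 30_000,
        "n_reads": 100_000,
        "protocol": {
            "mode": "emulsion",
            "template_molecules": 20_000,
            "micelle_count": 100_000_000,
            "cycles_round1": 15,
            "cycles_round2": 18,
            "carryover_fraction": 0.01,
            "switch_prob": 1e-3,
        },
    },
}
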