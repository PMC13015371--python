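"""End-to-end orchestration: simulate/ingest -> fit growth -> concordance -> report.

Every artifact lands in the configured output directory; a JSON manifest
records the config snapshot, artifact SHA-256 checksums, tool version and
timestamps.  Identical config + seed reproduces identical artifact bytes
(the manifest's timestamps are the only run-varying output).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .concordance import (
    apply_thresholds,
    classify_concordance,
    concordance_report,
    partition_to_dataframe,
    read_contrast_table,
)
from .config import PipelineConfig
from .errors import NpcscreenError
from .growth import GrowthExperiment, read_traces_csv, write_traces_csv
from .simulate import simulate_deg_tables, simulate_well_traces

log = logging.getLogger("npcscreen")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, artifacts with checksums, version."""

    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    version: str = __version__
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageFailure(NpcscreenError, RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Stages run in order (growth data, growth analysis, DEG data, concordance,
    report); any stage failure aborts with the stage name, and the partial
    manifest records the failure.
    """
    out = Path(out_dir if out_dir is not None else config.io.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        started=datetime.now(timezone.utc).isoformat(),
    )

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.artifacts[name] = _sha256(path)
        log.info("wrote %s", path)
        return path

    stage = "growth-data"
    try:
        if config.io.traces_csv:
            src = Path(config.io.traces_csv)
            if not src.exists():
                raise FileNotFoundError(f"traces file not found: {src}")
            traces = read_traces_csv(src)
            truth = None
        else:
            traces, truth = simulate_well_traces(config.growth.sim)
            emit("traces.csv", lambda p: write_traces_csv(traces, p))
            emit("growth_truth.json", truth.to_json)

        stage = "fit-growth"
        experiment = GrowthExperiment(
            traces,
            min_span_h=config.growth.fit.min_span_h,
            min_replicates=config.growth.fit.min_replicates,
            fit_start_h=config.growth.fit.fit_start_h,
        )
        results = experiment.fit()
        for s in results.summaries:
            for well, reason in s.removed:
                log.info(
                    "outlier removal: plate=%s line=%s condition=%s well=%s rule=%s",
                    s.plate_id, s.line_id, s.condition, well, reason,
                )
        emit("well_fits.tsv", lambda p: results.fits_frame().to_csv(p, sep="\t", index=False))
        emit(
            "replicate_summaries.tsv",
            lambda p: results.summaries_frame().to_csv(p, sep="\t", index=False),
        )
        emit(
            "dt_comparisons.tsv",
            lambda p: results.comparisons_frame().to_csv(p, sep="\t", index=False),
        )
        stats: dict = {"n_comparisons": len(results.comparisons)}
        genotypes = sorted({c.genotype for c in results.comparisons})
        for gt in genotypes:
            changes = results.dt_changes(gt)
            stats[f"mean_dt_change_{gt}"] = sum(changes) / len(changes)
        if len(genotypes) == 2 and all(len(results.dt_changes(g)) > 0 for g in genotypes):
            u, p = results.mann_whitney_by_genotype(genotypes[1], genotypes[0])
            stats["mann_whitney_U"] = u
            stats["mann_whitney_p"] = p
        for gt in genotypes:
            if len(results.dt_changes(gt)) >= 3:
                try:
                    r, r2, p = results.ratio_correlation(gt)
                    stats[f"ratio_correlation_{gt}"] = {"r": r, "r_squared": r2, "p": p}
                except NpcscreenError:
                    pass
        emit("growth_stats.json", lambda p: p.write_text(json.dumps(stats, indent=1, sort_keys=True)))

        stage = "deg-data"
        if config.io.genotype_table and config.io.treatment_table:
            for candidate in (config.io.genotype_table, config.io.treatment_table):
                if not Path(candidate).exists():
                    raise FileNotFoundError(f"contrast table not found: {candidate}")
            genotype = read_contrast_table(config.io.genotype_table)
            treatment = read_contrast_table(config.io.treatment_table)
        else:
            genotype, treatment, deg_truth = simulate_deg_tables(config.deg.sim)
            emit("genotype_contrast.tsv", genotype.write_tsv)
            emit("treatment_contrast.tsv", treatment.write_tsv)
            emit("deg_truth.json", deg_truth.to_json)

        stage = "concordance"
        geno_thr = apply_thresholds(genotype, config.deg.genotype_thresholds)
        treat_thr = apply_thresholds(treatment, config.deg.treatment_thresholds)
        partition = classify_concordance(treat_thr, geno_thr)
        emit(
            "concordance_partition.tsv",
            lambda p: partition_to_dataframe(partition, treat_thr, geno_thr).to_csv(
                p, sep="\t", index=False
            ),
        )

        stage = "report"
        report = concordance_report(partition)
        emit(
            "concordance_summary.json",
            lambda p: p.write_text(json.dumps(report, indent=1, sort_keys=True)),
        )
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.to_json(out / "manifest.json")
        raise StageFailure(stage, exc) from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(out / "manifest.json")
    return manifest
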