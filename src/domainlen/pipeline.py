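"""End-to-end orchestration: simulate (or load) -> featurize -> fit ->
importance -> localize, with per-stage artifacts and a machine-readable
summary.

One global seed deterministically derives per-stage seeds by hashing the
stage name, so individual stages are reproducible in isolation and reruns
with the same configuration produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .features import build_feature_matrix, write_feature_matrix
from .importance import significant_features
from .intervals import read_bed, read_bedpe, write_bed, write_bedpe
from .length_model import ModelConfig, fit_length_model, observed_predicted_correlation
from .localization import length_bins, profile_report, relative_anchor_coverage
from .simulate import SimulationConfig, simulate_all

__all__ = ["RunConfig", "RunSummary", "run", "stage_seed"]

logger = logging.getLogger("domainlen")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed < 2**31 from the global seed and stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """One pipeline run: either real BED/BEDPE inputs or a simulation.

    Exactly one of ``simulation`` or (``domains_path`` + ``track_paths``)
    must be provided; ``anchors_path`` is optional for real runs.
    """

    out_dir: str | Path = "domainlen_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    domains_path: str | None = None
    track_paths: dict[str, str] = field(default_factory=dict)  # label -> BED path
    anchors_path: str | None = None
    model: ModelConfig | None = None
    importance_repeats: int = 1
    bins_k: int = 5
    grid: int = 100

    def validate(self) -> None:
        real = self.domains_path is not None or bool(self.track_paths)
        if self.simulation is not None and real:
            raise ValueError("provide either real input paths or a simulation config, not both")
        if self.simulation is None and not (self.domains_path and self.track_paths):
            raise ValueError("provide a simulation config, or both domains_path and track_paths")


@dataclass
class RunSummary:
    observed_predicted_correlation: float
    significant_features: list[str]
    n_domains: int
    n_features: int
    artifacts: dict[str, str]
    version: str
    seed: int
    stage_seeds: dict[str, int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run(config: RunConfig) -> RunSummary:
    """Execute all stages in order, writing artifacts under ``out_dir``.

    On failure, partial outputs are retained alongside a ``FAILED`` marker
    naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    artifacts: dict[str, str] = {}
    seeds = {s: stage_seed(config.seed, s) for s in ("simulate", "model", "importance")}

    current = "input"
    try:
        if config.simulation is not None:
            current = "simulate"
            sim_cfg = config.simulation
            if sim_cfg.seed == 0:
                sim_cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": seeds["simulate"]})
            logger.info("simulating %d domains (seed %d)", sim_cfg.n_domains, sim_cfg.seed)
            domains, tracks, anchors, truth = simulate_all(sim_cfg)
            write_bed(domains, out / "domains.bed")
            artifacts["domains"] = str(out / "domains.bed")
            for t in tracks:
                p = out / f"track_{t.label}.bed"
                write_bed(t, p)
                artifacts[f"track_{t.label}"] = str(p)
            write_bedpe(anchors, out / "anchors.bedpe")
            artifacts["anchors"] = str(out / "anchors.bedpe")
            truth.to_json(out / "truth.json")
            artifacts["truth"] = str(out / "truth.json")
        else:
            current = "load"
            logger.info("loading domains from %s", config.domains_path)
            domains = read_bed(config.domains_path, label="domains")
            tracks = [read_bed(p, label=l) for l, p in config.track_paths.items()]
            anchors = read_bedpe(config.anchors_path) if config.anchors_path else []

        current = "featurize"
        matrix = build_feature_matrix(domains, tracks)
        write_feature_matrix(matrix, out / "matrix.tsv")
        artifacts["matrix"] = str(out / "matrix.tsv")
        logger.info("feature matrix: %d domains x %d features", matrix.n_domains, matrix.n_features)

        current = "fit"
        model_cfg = config.model or ModelConfig(seed=seeds["model"])
        model = fit_length_model(matrix, model_cfg)
        r = observed_predicted_correlation(model)
        report = {
            "n_trees": model_cfg.n_trees,
            "seed": model_cfg.seed,
            "correlation_oob": r,
            "observed": model.observed.tolist(),
            "oob_predicted": model.oob_prediction.tolist(),
        }
        with open(out / "model_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        artifacts["model_report"] = str(out / "model_report.json")
        logger.info("observed-vs-predicted (OOB) r = %.4f", r)

        current = "importance"
        imp = significant_features(
            matrix, model_cfg, seed=seeds["importance"], repeats=config.importance_repeats
        )
        with open(out / "importance.json", "w") as fh:
            json.dump(imp.to_dict(), fh, indent=1)
        artifacts["importance"] = str(out / "importance.json")
        logger.info("significant features: %s", imp.significant_labels)

        current = "localize"
        if anchors:
            bins = length_bins(domains, k=config.bins_k)
            profile = relative_anchor_coverage(domains, bins, anchors, grid=config.grid)
            profile_report(profile, out / "anchor_profile.tsv")
            artifacts["anchor_profile"] = str(out / "anchor_profile.tsv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise StageError(current, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary = RunSummary(
        observed_predicted_correlation=r,
        significant_features=imp.significant_labels,
        n_domains=matrix.n_domains,
        n_features=matrix.n_features,
        artifacts=artifacts,
        version=__version__,
        seed=config.seed,
        stage_seeds=seeds,
    )
    summary.to_json(out / "summary.json")
    return summary
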