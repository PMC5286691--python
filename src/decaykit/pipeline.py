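"""End-to-end orchestration: simulate/load -> fit -> metric -> cluster -> enrich -> integrate.

A run is driven by a single YAML config (one reproducibility surface); every
stage writes its table under the output directory, and a manifest records
tool version, parameters, per-stage gene counts (total -> fittable ->
filter-passing -> differential) and sha256 checksums of every output, so a
run can be verified or any stage re-run from its persisted inputs.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .decay_model import fit_all, test_differential
from .expression_integration import (
    join_and_label,
    stability_expression_correlation,
    subset_summary,
)
from .io_formats import (
    read_expression,
    read_gmt,
    read_timecourse,
    write_table,
    write_timecourse,
)
from .profile_clustering import build_profile_matrix, kmeans_profiles
from .set_enrichment import enrich_all_sets
from .stability_metric import compute_metric
from .synthetic_data import (
    config_from_dict,
    config_to_dict,
    simulate_expression_ratios,
    simulate_gene_sets,
    simulate_timecourse,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("decaykit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run (parsed from YAML).

    Input paths may be omitted when the corresponding stage is driven by the
    simulator (``simulate`` section) or skipped.  Thresholds: ``alpha_fit``
    for the log-linear fit filter, ``fdr_threshold`` for differential decay,
    ``lfc_threshold`` for the up/down expression subsets; all as in the
    analysis defaults (0.05, 0.05, 2).
    """

    out_dir: str = "decaykit_run"
    simulate: dict | None = None  # SimulationConfig fields; None = load from paths
    matrix_path: str | None = None
    design_path: str | None = None
    sets_path: str | None = None
    expression_path: str | None = None
    alpha_fit: float = 0.05
    fdr_threshold: float = 0.05
    lfc_threshold: float = 2.0
    k_clusters: int = 2
    kmeans_restarts: int = 10
    min_set_size: int = 10
    universe_mode: str = "all"
    spikein_normalize: bool = False
    log_ratio_metric: bool = False
    exact_ranksum: str | bool = "auto"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["fit", "metric", "cluster", "enrich", "integrate"]
    )
    # simulator-driven auxiliary inputs (used when simulate is set and no paths given)
    sim_sets: dict = field(
        default_factory=lambda: {"n_sets": 50, "set_size": 50, "n_planted": 1}
    )
    sim_expression: dict = field(default_factory=lambda: {"coupling": 0.5, "lfc_sd": 1.0})

    def validate(self) -> None:
        for name in ("alpha_fit", "fdr_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if self.simulate is None and not (self.matrix_path and self.design_path):
            raise ValueError("either a 'simulate' section or matrix/design paths are required")
        for p in (self.matrix_path, self.design_path, self.sets_path, self.expression_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if "integrate" in self.stages and self.simulate is None and self.expression_path is None:
            raise ValueError("stage 'integrate' is enabled but no expression table is available")
        if "enrich" in self.stages and self.simulate is None and self.sets_path is None:
            raise ValueError("stage 'enrich' is enabled but no gene-set file is available")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return (and write) the manifest.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are retained and the partially written manifest is
    saved with a FAILED marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[decaykit:%(stage)s] %(message)s"))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha_fit": config.alpha_fit,
            "fdr_threshold": config.fdr_threshold,
            "lfc_threshold": config.lfc_threshold,
            "k_clusters": config.k_clusters,
            "min_set_size": config.min_set_size,
            "universe_mode": config.universe_mode,
            "spikein_normalize": config.spikein_normalize,
            "log_ratio_metric": config.log_ratio_metric,
        },
        "stages": {},
        "counts": {},
        "checksums": {},
    }
    stage = "setup"

    def info(msg: str) -> None:
        log.info(msg, extra={"stage": stage})

    def record(name: str, path: Path) -> None:
        manifest["checksums"][name] = _sha256(path)

    try:
        # ---- inputs: simulate or load --------------------------------
        collection = None
        expression = None
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = config_from_dict({**config.simulate, "seed": config.seed})
            dataset, truth = simulate_timecourse(sim_cfg)
            write_timecourse(dataset, out / "matrix.tsv", out / "design.tsv",
                             params={"seed": sim_cfg.seed})
            write_table(truth.table, out / "truth.tsv", params=config_to_dict(sim_cfg))
            record("matrix.tsv", out / "matrix.tsv")
            record("design.tsv", out / "design.tsv")
            record("truth.tsv", out / "truth.tsv")
            manifest["stages"]["simulate"] = "ok"
            if config.sets_path is None and "enrich" in config.stages:
                collection = simulate_gene_sets(
                    truth, seed=config.seed + 1, **config.sim_sets
                )
            if config.expression_path is None and "integrate" in config.stages:
                expression = simulate_expression_ratios(
                    truth, seed=config.seed + 2, **config.sim_expression
                )
        else:
            stage = "load"
            dataset = read_timecourse(config.matrix_path, config.design_path)
            manifest["stages"]["load"] = "ok"
        if config.sets_path is not None:
            collection = read_gmt(config.sets_path, universe=list(dataset.genes))
        if config.expression_path is not None:
            expression = read_expression(config.expression_path)
        manifest["counts"]["total"] = int((~dataset.spikein).sum())

        # ---- fit ------------------------------------------------------
        fits = None
        if "fit" in config.stages:
            stage = "fit"
            fits, summary = fit_all(
                dataset,
                alpha_fit=config.alpha_fit,
                normalize_spikein=config.spikein_normalize,
            )
            fits = test_differential(fits, fdr_threshold=config.fdr_threshold)
            write_table(fits, out / "fits.tsv",
                        params={"alpha_fit": config.alpha_fit, "fdr": config.fdr_threshold})
            record("fits.tsv", out / "fits.tsv")
            manifest["counts"].update(
                {
                    "fittable": summary.n_fittable,
                    "filter_passing": summary.n_retained,
                    "differential": int(fits["differential"].sum()),
                }
            )
            info(
                f"fit {summary.n_total} genes: {summary.n_fittable} fittable, "
                f"{summary.n_retained} passed filter, "
                f"{int(fits['differential'].sum())} differential"
            )
            manifest["stages"]["fit"] = "ok"

        # ---- metric ---------------------------------------------------
        metric = None
        if "metric" in config.stages and fits is not None:
            stage = "metric"
            metric = compute_metric(fits, use_log_ratio=config.log_ratio_metric)
            write_table(metric, out / "metric.tsv",
                        params={"pi0": round(metric.attrs["lfdr_pi0"], 4)})
            record("metric.tsv", out / "metric.tsv")
            manifest["stages"]["metric"] = "ok"

        # ---- cluster --------------------------------------------------
        if "cluster" in config.stages and fits is not None:
            stage = "cluster"
            if int(fits["differential"].sum()) >= config.k_clusters:
                profiles = build_profile_matrix(fits, differential_only=True)
                labels, centroids = kmeans_profiles(
                    profiles, k=config.k_clusters,
                    n_restarts=config.kmeans_restarts, seed=config.seed,
                )
                write_table(profiles.values, out / "profiles.tsv")
                write_table(labels.to_frame(), out / "clusters.tsv")
                write_table(centroids, out / "centroids.tsv")
                for f in ("profiles.tsv", "clusters.tsv", "centroids.tsv"):
                    record(f, out / f)
                manifest["stages"]["cluster"] = "ok"
            else:
                manifest["stages"]["cluster"] = "skipped (too few differential genes)"

        # ---- enrich ---------------------------------------------------
        if "enrich" in config.stages and metric is not None:
            stage = "enrich"
            if collection is None:
                raise ValueError("no gene sets available")
            enr = enrich_all_sets(
                metric, collection,
                min_size=config.min_set_size,
                universe_mode=config.universe_mode,
                exact=config.exact_ranksum,
            )
            write_table(enr, out / "enrichment.tsv")
            record("enrichment.tsv", out / "enrichment.tsv")
            manifest["stages"]["enrich"] = "ok"

        # ---- integrate ------------------------------------------------
        if "integrate" in config.stages and metric is not None:
            stage = "integrate"
            if expression is None:
                raise ValueError("no expression table available")
            joined = join_and_label(expression, metric, lfc_threshold=config.lfc_threshold)
            summary_tab = subset_summary(joined)
            rho, p = stability_expression_correlation(joined)
            write_table(joined, out / "integration.tsv")
            write_table(summary_tab, out / "integration_summary.tsv")
            record("integration.tsv", out / "integration.tsv")
            record("integration_summary.tsv", out / "integration_summary.tsv")
            manifest["stages"]["integrate"] = "ok"
            manifest["correlation"] = {"spearman_rho": rho, "pvalue": p}

        stage = "manifest"
        _check_funnel(manifest["counts"])
    except Exception as exc:
        manifest["stages"][stage] = "FAILED"
        manifest["error"] = str(exc)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _check_funnel(counts: dict) -> None:
    chain = [counts.get(k) for k in ("total", "fittable", "filter_passing", "differential")]
    chain = [c for c in chain if c is not None]
    if any(b > a for a, b in zip(chain, chain[1:])):
        raise ValueError(f"inconsistent gene-count funnel: {counts}")
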