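"""End-to-end pipeline: simulate → impute → mediate → cluster → report.

One YAML/`PipelineConfig` drives all stages; a single master seed fans out
to the stage seeds by fixed offsets (simulate +0, missingness handled
inside the scenario config, impute +10000, mediation +20000), so two runs
with the same config produce numerically identical artifacts. Every run
directory is self-describing: the effective config, per-stage seeds and
SHA-256 checksums of all artifacts land in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import cluster_frequency_matrix, frequency_matrix, render_heatmap, report
from .cohort import OUTCOMES, read_cohort, write_cohort
from .impute import chained_equations_impute
from .mediation import ANALYSIS_RF, RFParams, mediation_analysis
from .panel import builtin_panel
from .synthetic import ScenarioConfig, generate_cohort, inject_missingness, scenario_config

logger = logging.getLogger(__name__)

SEED_OFFSET_IMPUTE = 10_000
SEED_OFFSET_MEDIATE = 20_000

STAGES = ("simulate", "impute", "mediate", "cluster", "report")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; ``master_seed`` is mandatory
    (no wall-clock seeding)."""

    master_seed: int
    scenario: str = "full_mediation"  # preset name, or path to a cohort CSV
    scenario_overrides: dict = field(default_factory=dict)
    m: int = 5
    iterations: int = 10
    rf_params: RFParams = field(default_factory=lambda: ANALYSIS_RF)
    n_bootstrap: int = 50
    n_permutations: int = 19
    alpha: float = 0.05
    threshold: int | None = None
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOMES))
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    outdir: str = "run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.master_seed is None:
            raise ValueError("master_seed must be set explicitly")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        # scenario overrides are validated by ScenarioConfig at build time
        if not Path(self.scenario).exists() and self.scenario not in (
            "full_mediation", "partial_mediation", "null",
        ):
            raise ValueError(f"unknown scenario or missing file: {self.scenario!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rf = raw.pop("rf_params", None)
        cfg = cls(**raw)
        if rf is not None:
            cfg.rf_params = RFParams(**rf)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rf_params"] = dataclasses.asdict(self.rf_params)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonl_logger(run_dir: Path, level: str) -> logging.Logger:
    lg = logging.getLogger(f"cpgmediation.run.{run_dir.name}")
    lg.setLevel(level)
    lg.handlers.clear()
    handler = logging.FileHandler(run_dir / "pipeline.log.jsonl")

    class _JsonFmt(logging.Formatter):
        def format(self, record):
            return json.dumps(
                {"level": record.levelname, "stage": getattr(record, "stage", None),
                 "msg": record.getMessage()},
                sort_keys=True,
            )

    handler.setFormatter(_JsonFmt())
    lg.addHandler(handler)
    lg.propagate = False
    return lg


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; return (and write) the artifact manifest.

    A stage failure raises ``RuntimeError`` naming the stage; artifacts of
    completed stages are retained for debugging.
    """
    run_dir = Path(cfg.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    lg = _jsonl_logger(run_dir, cfg.log_level)
    manifest: dict = {
        "version": __version__,
        "master_seed": cfg.master_seed,
        "config": cfg.to_dict(),
        "stages": {},
        "files": {},
    }
    with open(run_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    panel = builtin_panel()
    current = "simulate"
    try:
        t0 = time.perf_counter()
        if Path(cfg.scenario).exists():
            cohort = read_cohort(cfg.scenario)
            scen = None
        else:
            scen = scenario_config(
                cfg.scenario, seed=cfg.master_seed, **cfg.scenario_overrides
            )
            cohort = inject_missingness(generate_cohort(scen, panel=panel), scen)
            scen.to_json(run_dir / "scenario.json")
        write_cohort(cohort, run_dir / "cohort.csv")
        manifest["stages"]["simulate"] = {
            "n": len(cohort), "seconds": round(time.perf_counter() - t0, 2),
        }
        lg.info("simulated cohort with %d rows", len(cohort), extra={"stage": current})

        current = "impute"
        t0 = time.perf_counter()
        stack = chained_equations_impute(
            cohort, m=cfg.m, iterations=cfg.iterations,
            seed=(cfg.master_seed + SEED_OFFSET_IMPUTE) % 2**31,
        )
        stack.save(run_dir / "stack")
        manifest["stages"]["impute"] = {
            "m": stack.m, "excluded": stack.excluded,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        lg.info("imputed m=%d datasets", stack.m, extra={"stage": current})

        current = "mediate"
        t0 = time.perf_counter()
        results = mediation_analysis(
            stack, panel=panel, outcomes=cfg.outcomes, rf_params=cfg.rf_params,
            n_bootstrap=cfg.n_bootstrap, n_permutations=cfg.n_permutations,
            alpha=cfg.alpha, seed=(cfg.master_seed + SEED_OFFSET_MEDIATE) % 2**31,
            threshold=cfg.threshold,
        )
        with open(run_dir / "results.json", "w") as fh:
            json.dump({o: r.to_dict() for o, r in results.items()}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["mediate"] = {
            "outcomes": list(results),
            "seconds": round(time.perf_counter() - t0, 2),
        }
        lg.info("mediation done for %d outcomes", len(results), extra={"stage": current})

        current = "cluster"
        t0 = time.perf_counter()
        fm = frequency_matrix(results, model="cpg+interv", panel=panel)
        fm.to_csv(run_dir / "frequency_matrix.csv")
        if min(fm.values.shape) >= 2:
            cr = cluster_frequency_matrix(fm, cfg.cluster_metric, cfg.cluster_method)
            render_heatmap(fm, cr, panel, run_dir / "heatmap")
            heatmap_file = "heatmap.png"
        else:
            # a single outcome (or column) cannot be clustered; keep input order
            import numpy as _np

            from .clustering import ClusterResult

            cr = ClusterResult(
                list(fm.values.index), list(fm.values.columns),
                _np.empty((0, 4)), _np.empty((0, 4)),
            )
            heatmap_file = None
            lg.info("matrix too small to cluster; skipped heatmap",
                    extra={"stage": current})
        manifest["stages"]["cluster"] = {
            "shape": list(fm.values.shape),
            "clustered": min(fm.values.shape) >= 2,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        lg.info("clustered %sx%s matrix", *fm.values.shape, extra={"stage": current})

        current = "report"
        t0 = time.perf_counter()
        report(results, fm, cr, run_dir / "report.md", panel=panel,
               heatmap_file=heatmap_file)
        manifest["stages"]["report"] = {"seconds": round(time.perf_counter() - t0, 2)}
        lg.info("report written", extra={"stage": current})
    except Exception as err:
        lg.error("stage failed: %s", err, extra={"stage": current})
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(run_dir))] = _sha256(p)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
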