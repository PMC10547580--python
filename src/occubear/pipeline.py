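"""End-to-end orchestration: simulate/ingest -> screen -> fit -> summarize -> map.

One :class:`PipelineConfig` (built in code or from YAML) drives the whole
analysis with a single seed; every output file carries the config hash and
seed so a run is auditable and re-running the same config is idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data_io, idw, model, screening, simulate, summaries

log = logging.getLogger("occubear")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "occubear_run"
    seed: int = 0
    detections_path: str | None = None
    covariates_path: str | None = None
    scenario: simulate.SimulationScenario | None = None
    screening_threshold: float = 0.7
    mcmc: model.MCMCConfig = field(default_factory=model.MCMCConfig)
    priors: model.Priors = field(default_factory=model.Priors)
    pixel_size: float = 1000.0
    idw_power: float = 2.0
    days_per_occasion: int = 7
    strict: bool = False

    def __post_init__(self) -> None:
        has_paths = self.detections_path is not None or self.covariates_path is not None
        if has_paths and self.scenario is not None:
            raise ValueError("give input paths OR a simulation scenario, not both")
        if not has_paths and self.scenario is None:
            self.scenario = simulate.SimulationScenario(seed=self.seed)
        if has_paths and (self.detections_path is None or self.covariates_path is None):
            raise ValueError("both detections and covariates paths are required")
        # one master seed drives independent streams for simulation and MCMC
        sim_seed, mcmc_seed = (
            int(s) for s in np.random.SeedSequence(self.seed).generate_state(2) % (2**31)
        )
        if self.scenario is not None:
            self.scenario.seed = sim_seed
        self.mcmc.seed = mcmc_seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        for key in ("out_dir", "seed", "screening_threshold", "pixel_size",
                    "idw_power", "days_per_occasion", "strict"):
            if key in raw:
                kw[key] = raw[key]
        inputs = raw.get("inputs") or {}
        if inputs:
            kw["detections_path"] = inputs.get("detections")
            kw["covariates_path"] = inputs.get("covariates")
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            if "extent" in sc:
                sc["extent"] = tuple(sc["extent"])
            if "beta" in sc:
                sc["beta"] = np.asarray(sc["beta"], dtype=float)
            kw["scenario"] = simulate.SimulationScenario(**sc)
        if "mcmc" in raw:
            kw["mcmc"] = model.MCMCConfig(**raw["mcmc"])
        if "priors" in raw:
            kw["priors"] = model.Priors(**raw["priors"])
        return cls(**kw)

    def config_hash(self) -> str:
        d = asdict(self)
        if d.get("scenario") is not None:
            d["scenario"]["beta"] = list(np.asarray(d["scenario"]["beta"], dtype=float))
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    history: data_io.DetectionHistory
    covariates: data_io.SiteCovariates
    screen: screening.CorrelationReport
    chains: model.PosteriorChains
    summary: model.FitSummary
    naive: summaries.NaiveSiteStats
    dataset: summaries.DatasetSummary
    surface: idw.DetectionSurface
    files: dict[str, str]

    @property
    def converged(self) -> bool:
        return self.summary.converged


def _stage(name: str):
    def wrap(fn):
        def inner(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash()} seed={config.seed}"
    files: dict[str, str] = {}

    def record(name: str, path: Path) -> Path:
        files[name] = str(path)
        return path

    # --- ingest or simulate -------------------------------------------
    if config.scenario is not None:
        ds = _stage("simulate")(simulate.simulate_dataset)(config.scenario)
        history, cov = ds.detection_history, ds.covariates
        paths = simulate.write_dataset(ds, out, header=tag)
        files.update(paths)
    else:
        history = _stage("ingest")(data_io.read_detection_matrix)(config.detections_path)
        cov = data_io.read_covariates(config.covariates_path, history)
        data_io.write_detection_matrix(history, record("detections", out / "detections.csv"), header=tag)
        data_io.write_covariates(cov, record("covariates", out / "covariates.csv"), header=tag)
    log.info("data: %d sites x %d occasions", history.n_sites, history.n_occasions)

    # --- collinearity screen ------------------------------------------
    screen = _stage("screen")(screening.correlation_screen)(cov, config.screening_threshold)
    screen.to_csv(record("screening", out / "screening.csv"), header=tag)
    if screen.any_flagged:
        log.warning("collinear predictor pairs flagged:\n%s", screen.flagged)

    # --- fit ----------------------------------------------------------
    std_cov, std_spec = data_io.standardize(cov)
    chains = _stage("fit")(model.run_mcmc)(history, std_cov, config.mcmc, config.priors)
    chains.to_dataframe().to_csv(record("chains", out / "chains.csv"), index=False)
    summary = model.summarize_posterior(chains)
    summary.to_csv(record("summary", out / "summary.csv"), header=tag)
    conv = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rhat": {k: _jsonify(v) for k, v in summary.table["rhat"].items()},
        "rhat_threshold": config.mcmc.rhat_threshold,
        "converged": summary.converged,
        "mean_acceptance": float(chains.acceptance.mean()),
    }
    record("convergence", out / "convergence.json").write_text(json.dumps(conv, indent=2))
    log.info("posterior:\n%s", summary)
    if not summary.converged:
        log.warning("convergence flag is FALSE (some Rhat >= %.2f)", config.mcmc.rhat_threshold)

    # --- naive summaries ----------------------------------------------
    naive = _stage("summarize")(summaries.site_detection_proportions)(history)
    naive.to_csv(record("naive_sites", out / "naive_sites.csv"), header=tag)
    dset = summaries.dataset_summary(history, config.days_per_occasion)
    record("dataset_summary", out / "dataset_summary.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed,
                    **{k: _jsonify(v) for k, v in asdict(dset).items()},
                    "naive_occupancy": dset.naive_occupancy}, indent=2)
    )
    log.info("%s", dset)

    # --- detection-probability surface --------------------------------
    grid = idw.GridSpec.covering(cov.coords(), pixel_size=config.pixel_size,
                                 power=config.idw_power)
    surface = _stage("map")(idw.idw_interpolate)(cov.coords(), naive.values(), grid)
    surface.write_csv(record("surface_csv", out / "surface.csv"), header=tag)
    surface.write_ascii_grid(record("surface_asc", out / "surface.asc"))

    # --- manifest ------------------------------------------------------
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "standardization": {
            "mean": {k: float(v) for k, v in std_spec.means.items()},
            "sd": {k: float(v) for k, v in std_spec.sds.items()},
        },
        "files": files,
    }
    record("manifest", out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config, history=history, covariates=cov, screen=screen,
        chains=chains, summary=summary, naive=naive, dataset=dset,
        surface=surface, files=files,
    )


def _jsonify(v):
    if isinstance(v, (np.floating, float)):
        return None if not np.isfinite(v) else float(v)
    if isinstance(v, (np.integer, int)):
        return int(v)
    return v
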