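"""Synthetic camera-trap datasets with a known occupancy-covariate relationship.

The generator emulates the survey design the rest of the package analyses:
152 camera sites surveyed over a 21-day deployment collapsed to 3 weekly
occasions, seven site covariates whose marginal moments match the field
study's printed means/SDs, a latent occupancy state drawn from a
logit-linear model in the *standardized* covariates, and conditionally
independent Bernoulli detections at occupied sites.

Covariate families are moment-matched:

* canopy cover — normal truncated to [0, 100], with the underlying (mu,
  sigma) solved numerically so the truncated law itself has the target
  mean/SD;
* human and livestock counts — negative binomial (heavy-tailed, SD >> mean);
* large-predator detection proportion — a three-point mixture on {0, 2/3, 1}
  (near-Bernoulli; a proportion with SD ~ 0.48 on [0, 1] is necessarily
  bimodal);
* distances — lognormal, matched by moments in closed form.

Every family can be overridden per covariate through
``SimulationScenario.covariate_spec``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .data_io import (
    PREDICTOR_COLUMNS,
    DetectionHistory,
    SiteCovariates,
    standardize,
    write_covariates,
    write_detection_matrix,
)

__all__ = [
    "BETA_NAMES",
    "DEFAULT_BETA",
    "DEFAULT_COVARIATE_SPEC",
    "SimulationScenario",
    "SimulatedDataset",
    "simulate_covariates",
    "simulate_detections",
    "simulate_dataset",
    "write_dataset",
]

#: Coefficient order: intercept then the seven predictors, matching
#: :data:`occubear.data_io.PREDICTOR_COLUMNS`.
BETA_NAMES = ["beta0", *(f"beta_{c}" for c in PREDICTOR_COLUMNS)]

# Defaults follow the study's fitted model: intercept at logit of the
# estimated occupancy 0.15; slopes are the reported posterior means on the
# standardized scale (cc 1.00, livestock -2.24, predators 3.01, human 1.42,
# settlement 0.36, road 0.06, water 0.46); per-occasion detection 0.319.
DEFAULT_BETA = np.array([float(logit(0.15)), 1.00, -2.24, 3.01, 1.42, 0.36, 0.06, 0.46])

DEFAULT_COVARIATE_SPEC: dict[str, dict] = {
    "cc": {"family": "truncnorm", "mean": 42.19, "sd": 21.36, "low": 0.0, "high": 100.0},
    "human": {"family": "negbin", "mean": 76.72, "sd": 244.55},
    "livestock": {"family": "negbin", "mean": 36.74, "sd": 102.45},
    "predators": {
        "family": "mixture",
        "values": [0.0, 2.0 / 3.0, 1.0],
        # weights solve mean = 0.37, SD = 0.48 exactly on this support
        "weights": [0.62595, 0.01215, 0.36190],
    },
    "d_settlement": {"family": "lognormal", "mean": 2182.80, "sd": 1691.33},
    "d_road": {"family": "lognormal", "mean": 741.69, "sd": 1138.91},
    "d_water": {"family": "lognormal", "mean": 3354.83, "sd": 2213.63},
}


@dataclass
class SimulationScenario:
    """Design of one synthetic survey.

    ``beta`` lives in standardized-covariate space (logit units); ``extent``
    is (x_min, y_min, x_max, y_max) in projected metres.
    """

    n_sites: int = 152
    n_occasions: int = 3
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    p_true: float = 0.319
    covariate_spec: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_SPEC.items()})
    extent: tuple[float, float, float, float] = (0.0, 0.0, 60_000.0, 40_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        if not 0.0 < self.p_true < 1.0:
            raise ValueError("p_true must lie strictly in (0, 1)")
        if self.beta.shape != (8,):
            raise ValueError(
                "beta must have length 8: intercept plus slopes for "
                + ", ".join(PREDICTOR_COLUMNS)
            )
        unknown = set(self.covariate_spec) - set(PREDICTOR_COLUMNS)
        if unknown:
            raise ValueError(f"covariate_spec has unknown predictors: {sorted(unknown)}")
        missing = set(PREDICTOR_COLUMNS) - set(self.covariate_spec)
        if missing:
            raise ValueError(f"covariate_spec missing predictors: {sorted(missing)}")
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("extent must be (x_min, y_min, x_max, y_max) with positive area")


@dataclass
class SimulatedDataset:
    detection_history: DetectionHistory
    covariates: SiteCovariates
    z_true: np.ndarray
    psi_true: np.ndarray
    scenario: SimulationScenario


def _truncnorm_params(mean: float, sd: float, low: float, high: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so the [low, high]-truncated normal has the target moments."""

    def resid(q):
        mu, log_sigma = q
        sigma = np.exp(log_sigma)
        a, b = (low - mu) / sigma, (high - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - hybr converges for sane inputs
        raise ValueError(f"truncated-normal moment matching failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_covariate(name: str, spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    family = spec.get("family")
    if family == "constant":
        return np.full(n, float(spec["value"]))
    if family == "normal":
        _check_sd(name, spec)
        return rng.normal(spec["mean"], spec["sd"], size=n)
    if family == "truncnorm":
        _check_sd(name, spec)
        low, high = float(spec["low"]), float(spec["high"])
        mu, sigma = _truncnorm_params(float(spec["mean"]), float(spec["sd"]), low, high)
        a, b = (low - mu) / sigma, (high - mu) / sigma
        return stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(size=n, random_state=rng)
    if family == "negbin":
        _check_sd(name, spec)
        m, v = float(spec["mean"]), float(spec["sd"]) ** 2
        if v <= m:
            raise ValueError(
                f"{name}: negative binomial needs SD^2 > mean "
                f"(got mean={m}, SD^2={v})"
            )
        r = m * m / (v - m)
        return rng.negative_binomial(r, r / (r + m), size=n).astype(float)
    if family == "lognormal":
        _check_sd(name, spec)
        m, s = float(spec["mean"]), float(spec["sd"])
        if m <= 0:
            raise ValueError(f"{name}: lognormal needs mean > 0 (got {m})")
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if family == "mixture":
        values = np.asarray(spec["values"], dtype=float)
        weights = np.asarray(spec["weights"], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError(f"{name}: mixture weights must be non-negative and sum > 0")
        return rng.choice(values, size=n, p=weights / weights.sum())
    raise ValueError(f"{name}: unknown distribution family {family!r}")


def _check_sd(name: str, spec: dict) -> None:
    if float(spec["sd"]) <= 0:
        raise ValueError(f"{name}: SD must be > 0 (got {spec['sd']})")


def simulate_covariates(scenario: SimulationScenario) -> SiteCovariates:
    """Draw one covariate table; coordinates uniform over the scenario extent."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_sites
    x0, y0, x1, y1 = scenario.extent
    data = {
        "site_id": [f"site_{i + 1:04d}" for i in range(n)],
        "x": rng.uniform(x0, x1, size=n),
        "y": rng.uniform(y0, y1, size=n),
    }
    for col in PREDICTOR_COLUMNS:
        data[col] = _draw_covariate(col, scenario.covariate_spec[col], n, rng)
    return SiteCovariates(pd.DataFrame(data))


def simulate_detections(
    covariates: SiteCovariates, scenario: SimulationScenario
) -> SimulatedDataset:
    """Draw latent occupancy and the detection matrix given covariates.

    Occupancy: z_i ~ Bernoulli(psi_i), logit(psi_i) = beta . x_i with x_i the
    standardized predictors (plus intercept).  Detection: given z_i = 1 each
    occasion is an independent Bernoulli(p_true); given z_i = 0 all zeros.
    """
    # separate stream from the covariate draw so the same covariates can be
    # reused across detection replicates
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    constant = covariates.table[PREDICTOR_COLUMNS].std(ddof=1) == 0
    if constant.all():
        # degenerate all-constant design: linear predictor is the intercept
        psi = np.full(covariates.n_sites, expit(scenario.beta[0]))
    else:
        std_cov, _ = standardize(covariates)
        X = np.column_stack(
            [np.ones(covariates.n_sites), std_cov.predictor_matrix()]
        )
        psi = expit(X @ scenario.beta)
    z = rng.random(covariates.n_sites) < psi
    dets = (
        rng.random((covariates.n_sites, scenario.n_occasions)) < scenario.p_true
    ) & z[:, None]
    mat = pd.DataFrame(
        dets.astype(float),
        columns=[f"occ_{j + 1}" for j in range(scenario.n_occasions)],
    )
    history = DetectionHistory(site_ids=covariates.site_ids, occasion_matrix=mat)
    return SimulatedDataset(
        detection_history=history,
        covariates=covariates,
        z_true=z.astype(np.int64),
        psi_true=psi,
        scenario=scenario,
    )


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """Covariates and detections in one call."""
    return simulate_detections(simulate_covariates(scenario), scenario)


def write_dataset(ds: SimulatedDataset, outdir, header: str | None = None) -> dict[str, str]:
    """Write detections.csv, covariates.csv, truth.csv under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = header or f"seed={ds.scenario.seed}"
    paths = {
        "detections": out / "detections.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.csv",
    }
    write_detection_matrix(ds.detection_history, paths["detections"], header=tag)
    write_covariates(ds.covariates, paths["covariates"], header=tag)
    truth = pd.DataFrame(
        {
            "site_id": ds.covariates.site_ids,
            "psi_true": ds.psi_true,
            "z_true": ds.z_true,
        }
    )
    with open(paths["truth"], "w") as fh:
        fh.write(f"# {tag}\n")
        truth.to_csv(fh, index=False)
    return {k: str(v) for k, v in paths.items()}


def vary(scenario: SimulationScenario, **changes) -> SimulationScenario:
    """A copy of ``scenario`` with fields replaced (convenience for studies)."""
    return replace(scenario, **changes)
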