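"""Synthetic route-count datasets with outbreak-pulse defoliation.

Generates multi-stratum, multi-route, multi-observer count series from
the same hierarchical overdispersed-Poisson model that the inference
module fits, together with defoliation covariates shaped like an insect
outbreak: a trapezoidal pulse (linear ramp up, plateau, linear ramp
down) on the proportion scale, with route-to-route heterogeneity applied
on the logit scale so proportions stay in [0, 1]. Because the ground
truth is recorded, every downstream stage — covariate construction,
filtering, MCMC fitting, trajectory estimation — can be scored against
known parameter values.

Years are integer indices 1..n_years. Observer turnover is a Bernoulli
renewal per route-year: with the configured probability a new
observer–route identity begins, and the model's first-year indicator I2
is set in exactly the first surveyed year of each identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._rng import stream
from .covariates import CovariateTable, build_covariate_table

__all__ = [
    "GroundTruth",
    "OutbreakConfig",
    "SimulationConfig",
    "LatentTruth",
    "generate_defoliation",
    "assign_observers",
    "generate_counts",
    "simulate_dataset",
    "save_dataset",
]

COUNT_COLUMNS = ["stratum", "route", "obsroute", "year", "count", "first_year"]


@dataclass
class GroundTruth:
    """True parameter values for a simulation.

    Effects are on the log-count scale. ``B1``/``B2`` are the across-strata
    mean local and regional defoliation effects from which per-stratum
    slopes are drawn (unless given explicitly); ``gamma0_mean``/``gamma0_sd``
    set the initial level of the first-difference year-effect random walk,
    i.e. baseline log abundance.
    """

    B1: float = 1.1
    B2: float = 0.5
    sigma_B1: float = 0.2
    sigma_B2: float = 0.2
    sigma_lambda: float = 0.1
    sigma_omega: float = 0.3
    sigma_eps: float = 0.2
    zeta: float = -0.2
    gamma0_mean: float = 0.7
    gamma0_sd: float = 0.3
    beta1_by_stratum: tuple | None = None
    beta2_by_stratum: tuple | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_B1", "sigma_B2", "sigma_lambda", "sigma_omega", "sigma_eps", "gamma0_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class OutbreakConfig:
    """Shape of the defoliation pulse shared by all strata.

    The pulse occupies years ``pulse_start .. pulse_start+pulse_length-1``
    with a trapezoidal profile; peak amplitudes are set separately for the
    local (route buffer) and regional (stratum) proportions, and each
    route's local series is offset around the stratum profile on the logit
    scale with SD ``route_heterogeneity_sd``.
    """

    pulse_start: int = 8
    pulse_length: int = 12
    peak_local_proportion: float = 0.8
    peak_regional_proportion: float = 0.6
    route_heterogeneity_sd: float = 0.75

    def __post_init__(self) -> None:
        if self.pulse_length < 1:
            raise ValueError("pulse_length must be >= 1")
        for name in ("peak_local_proportion", "peak_regional_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.route_heterogeneity_sd < 0:
            raise ValueError("route_heterogeneity_sd must be >= 0")

    @classmethod
    def default_for(cls, n_years: int) -> "OutbreakConfig":
        """Default pulse scaled to the year range: onset ~25% in, ~40% long.

        For the default 30-year design this gives years 8-19, mimicking a
        decade-scale outbreak rising mid-record.
        """
        start = max(2, round(0.25 * n_years))
        length = min(max(3, round(0.4 * n_years)), n_years - start + 1)
        return cls(pulse_start=start, pulse_length=length)


@dataclass
class SimulationConfig:
    """Dimensions and nuisance structure of a simulated survey."""

    n_strata: int = 6
    routes_per_stratum: int = 20
    n_years: int = 30
    first_regional_year: int = 5
    observer_turnover_prob: float = 0.1
    survey_prob: float = 1.0
    truth: GroundTruth = field(default_factory=GroundTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strata", "routes_per_stratum", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.first_regional_year < 2:
            raise ValueError("first_regional_year must be >= 2")
        if not 0.0 <= self.observer_turnover_prob <= 1.0:
            raise ValueError("observer_turnover_prob must lie in [0, 1]")
        if not 0.0 < self.survey_prob <= 1.0:
            raise ValueError("survey_prob must lie in (0, 1]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.n_years + 1)

    def route_ids(self) -> pd.DataFrame:
        strata = np.repeat(np.arange(1, self.n_strata + 1), self.routes_per_stratum)
        routes = np.arange(1, strata.size + 1)
        return pd.DataFrame({"stratum": strata, "route": routes})


def _pulse_shape(years: np.ndarray, start: int, length: int) -> np.ndarray:
    """Trapezoid in [0, 1]: ramps of ~length/4 years around a plateau."""
    ramp = max(1, length // 4)
    p = years - start
    inside = (p >= 0) & (p < length)
    shape = np.minimum(1.0, np.minimum((p + 1) / ramp, (length - p) / ramp))
    return np.where(inside, np.clip(shape, 0.0, 1.0), 0.0)


def generate_defoliation(
    config: SimulationConfig, outbreak: OutbreakConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate local and regional defoliation tables.

    Returns ``(local, regional)``: per-route-per-year local proportions
    (stratum, route, year, b1) and per-stratum annual regional proportions
    (stratum, year, b2_raw). Outside the pulse window every proportion is
    exactly zero; inside it the stratum mean of the route proportions
    tracks the stratum profile (peak ``peak_local_proportion``) and the
    regional series follows the same trapezoid scaled to
    ``peak_regional_proportion``.
    """
    years = config.years
    if outbreak.pulse_start < 1 or outbreak.pulse_start + outbreak.pulse_length - 1 > config.n_years:
        raise ValueError("pulse window must lie within 1..n_years")

    shape = _pulse_shape(years, outbreak.pulse_start, outbreak.pulse_length)
    local_profile = outbreak.peak_local_proportion * shape
    regional_profile = outbreak.peak_regional_proportion * shape

    routes = config.route_ids()
    rng = stream(config.seed, "defoliation", "route_offsets")
    offsets = rng.normal(0.0, outbreak.route_heterogeneity_sd, size=len(routes))

    n_routes = len(routes)
    rec_stratum = np.repeat(routes["stratum"].to_numpy(), len(years))
    rec_route = np.repeat(routes["route"].to_numpy(), len(years))
    rec_year = np.tile(years, n_routes)

    prof = np.tile(local_profile, n_routes)
    if outbreak.route_heterogeneity_sd == 0.0:
        b1 = prof
    else:
        off = np.repeat(offsets, len(years))
        tiny = 1e-9
        with np.errstate(divide="ignore"):
            b1 = expit(logit(np.clip(prof, tiny, 1 - tiny)) + off)
        b1 = np.where(prof == 0.0, 0.0, b1)

    local = pd.DataFrame(
        {"stratum": rec_stratum, "route": rec_route, "year": rec_year, "b1": b1}
    )
    regional = pd.DataFrame(
        {
            "stratum": np.repeat(np.arange(1, config.n_strata + 1), len(years)),
            "year": np.tile(years, config.n_strata),
            "b2_raw": np.tile(regional_profile, config.n_strata),
        }
    )
    return local, regional


def assign_observers(config: SimulationConfig) -> pd.DataFrame:
    """Assign observer–route identities and first-year flags to route-years.

    Returns one row per surveyed route-year with columns (stratum, route,
    obsroute, year, first_year). first_year is 1 in exactly the first
    surveyed year of each observer–route identity. With ``survey_prob < 1``
    route-years are dropped independently (missing surveys); a route's
    first surveyed year always starts a new identity.
    """
    rng = stream(config.seed, "observers")
    routes = config.route_ids()
    rows: list[tuple] = []
    next_id = 1
    for stratum, route in routes.itertuples(index=False):
        surveyed = config.years
        if config.survey_prob < 1.0:
            mask = rng.random(config.n_years) < config.survey_prob
            if not mask.any():
                mask[rng.integers(config.n_years)] = True
            surveyed = config.years[mask]
        current = None
        for k, year in enumerate(surveyed):
            turnover = k == 0 or rng.random() < config.observer_turnover_prob
            if turnover:
                current = next_id
                next_id += 1
            rows.append((stratum, route, current, int(year), 1 if turnover else 0))
    return pd.DataFrame(rows, columns=["stratum", "route", "obsroute", "year", "first_year"])


@dataclass
class LatentTruth:
    """Simulated latent values, aligned so recovery can be scored.

    ``gamma`` is a (stratum, year, gamma) frame, ``omega`` an (obsroute,
    omega) frame, ``beta1``/``beta2`` map stratum -> slope, and ``eps`` /
    ``eta`` are aligned row-wise with the emitted count table.
    """

    truth: GroundTruth
    gamma: pd.DataFrame
    omega: pd.DataFrame
    beta1: dict
    beta2: dict
    eps: np.ndarray
    eta: np.ndarray

    def to_json(self) -> str:
        payload = {
            "truth": asdict(self.truth),
            "gamma": self.gamma.to_dict(orient="list"),
            "omega": self.omega.to_dict(orient="list"),
            "beta1": {str(k): v for k, v in self.beta1.items()},
            "beta2": {str(k): v for k, v in self.beta2.items()},
            "eps": np.asarray(self.eps).tolist(),
            "eta": np.asarray(self.eta).tolist(),
        }
        return json.dumps(payload)


def generate_counts(
    config: SimulationConfig, covariates: CovariateTable
) -> tuple[pd.DataFrame, LatentTruth]:
    """Draw Poisson counts from the generative model.

    log(lambda) = gamma_{i,t} + beta1_i*b1 + beta2_i*I1*b2 + omega_j
    + zeta*I2 + eps, with counts Poisson(lambda). The covariate table must
    cover every stratum-route-year in the survey design.
    """
    truth = config.truth
    design = assign_observers(config)

    merged = design.merge(
        covariates.route_year, on=["stratum", "route", "year"], how="left", validate="m:1"
    ).merge(covariates.stratum_year, on=["stratum", "year"], how="left", validate="m:1")
    if merged[["b1", "b2", "I1"]].isna().any().any():
        missing = merged[merged["b1"].isna()][["stratum", "route", "year"]].head()
        raise ValueError(f"covariates do not cover the survey design; e.g.\n{missing}")

    strata = np.arange(1, config.n_strata + 1)
    n_years = config.n_years

    rng_beta = stream(config.seed, "betas")
    if truth.beta1_by_stratum is not None:
        beta1 = np.asarray(truth.beta1_by_stratum, dtype=float)
    else:
        beta1 = rng_beta.normal(truth.B1, truth.sigma_B1, size=config.n_strata)
    if truth.beta2_by_stratum is not None:
        beta2 = np.asarray(truth.beta2_by_stratum, dtype=float)
    else:
        beta2 = rng_beta.normal(truth.B2, truth.sigma_B2, size=config.n_strata)
    if beta1.size != config.n_strata or beta2.size != config.n_strata:
        raise ValueError("per-stratum beta vectors must have length n_strata")

    rng_gamma = stream(config.seed, "gamma")
    gamma = np.empty((config.n_strata, n_years))
    gamma[:, 0] = rng_gamma.normal(truth.gamma0_mean, truth.gamma0_sd, size=config.n_strata)
    steps = rng_gamma.normal(0.0, truth.sigma_lambda, size=(config.n_strata, n_years - 1))
    gamma[:, 1:] = gamma[:, [0]] + np.cumsum(steps, axis=1)

    obsroutes = np.sort(design["obsroute"].unique())
    rng_omega = stream(config.seed, "omega")
    omega = rng_omega.normal(0.0, truth.sigma_omega, size=obsroutes.size)
    omega_of = dict(zip(obsroutes.tolist(), omega.tolist()))

    i_pos = merged["stratum"].to_numpy() - 1
    t_pos = merged["year"].to_numpy() - 1
    rng_eps = stream(config.seed, "eps")
    eps = rng_eps.normal(0.0, truth.sigma_eps, size=len(merged))

    eta = (
        gamma[i_pos, t_pos]
        + beta1[i_pos] * merged["b1"].to_numpy()
        + beta2[i_pos] * merged["I1"].to_numpy() * merged["b2"].to_numpy()
        + np.vectorize(omega_of.get)(merged["obsroute"].to_numpy())
        + truth.zeta * merged["first_year"].to_numpy()
        + eps
    )
    rng_counts = stream(config.seed, "counts")
    counts = rng_counts.poisson(np.exp(eta))

    out = merged[["stratum", "route", "obsroute", "year", "first_year"]].copy()
    out["count"] = counts.astype(int)
    out = out[COUNT_COLUMNS]

    latent = LatentTruth(
        truth=truth,
        gamma=pd.DataFrame(
            {
                "stratum": np.repeat(strata, n_years),
                "year": np.tile(np.arange(1, n_years + 1), config.n_strata),
                "gamma": gamma.ravel(),
            }
        ),
        omega=pd.DataFrame({"obsroute": obsroutes, "omega": omega}),
        beta1=dict(zip(strata.tolist(), beta1.tolist())),
        beta2=dict(zip(strata.tolist(), beta2.tolist())),
        eps=eps,
        eta=eta,
    )
    return out, latent


def simulate_dataset(
    config: SimulationConfig, outbreak: OutbreakConfig | None = None
) -> tuple[pd.DataFrame, CovariateTable, LatentTruth]:
    """Full synthetic dataset: counts, assembled covariates, latent truth.

    The covariate cutoff is ``first_regional_year - 1`` so the era
    indicator switches on at ``first_regional_year`` (provided the 4-year
    trailing window is complete by then).
    """
    outbreak = outbreak or OutbreakConfig.default_for(config.n_years)
    local, regional = generate_defoliation(config, outbreak)
    cov = build_covariate_table(local, regional, cutoff=config.first_regional_year - 1)
    counts, latent = generate_counts(config, cov)
    return counts, cov, latent


def save_dataset(
    directory: str | Path,
    counts: pd.DataFrame,
    cov: CovariateTable,
    latent: LatentTruth | None = None,
) -> dict:
    """Write counts/covariates as CSV (and truth as JSON); return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.csv",
        "route_year": directory / "covariates_route_year.csv",
        "stratum_year": directory / "covariates_stratum_year.csv",
    }
    counts.to_csv(paths["counts"], index=False)
    cov.route_year.to_csv(paths["route_year"], index=False)
    cov.stratum_year.to_csv(paths["stratum_year"], index=False)
    if latent is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(latent.to_json())
    return paths
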