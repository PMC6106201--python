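"""Hierarchical overdispersed-Poisson count model.

The count on route j in stratum i and year t is Poisson with log-mean

    log(lambda_{i,j,t}) = gamma_{i,t} + beta1_i * b1_{i,j,t}
                          + beta2_i * I1(t) * b2_{i,t}
                          + omega_j + zeta * I2(j,t) + eps_{i,j,t}

where gamma is a per-stratum first-difference (random-walk) year effect,
omega a mean-zero observer-route intercept, zeta a scalar first-year
observer effect, and eps a mean-zero observation-level effect that makes
the counts overdispersed. Stratum slopes beta1_i, beta2_i are drawn from
common hyperdistributions N(B1, sigma_B1^2), N(B2, sigma_B2^2). The
"naive" variant omits the beta terms and the defoliation predictors but
is otherwise identical.

Priors: the first year of each gamma chain is Normal(0, sigma_lambda^2 *
inflation) with inflation 1000, i.e. effectively flat relative to the
between-year innovation; B1, B2 and zeta get diffuse mean-zero normals;
every standard deviation gets a uniform prior on (0, sd_upper].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .covariates import CovariateTable

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "PercentChange",
    "log_mean",
    "linear_predictor",
    "log_posterior",
    "percent_change",
]

VARIANTS = ("budworm", "naive")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the prior distributions.

    ``sd_B1``/``sd_B2``/``sd_zeta`` are the SDs of the mean-zero normal
    priors on B1, B2 and zeta; ``sd_upper`` bounds the uniform priors on
    all model SDs; ``gamma1_variance_inflation`` multiplies the year-effect
    innovation variance in the prior for the first year of each chain.
    """

    sd_B1: float = 10.0
    sd_B2: float = 10.0
    sd_zeta: float = 10.0
    sd_upper: float = 10.0
    variance_prior_family: str = "uniform-on-sd"
    gamma1_variance_inflation: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("sd_B1", "sd_B2", "sd_zeta", "sd_upper", "gamma1_variance_inflation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.variance_prior_family != "uniform-on-sd":
            raise NotImplementedError(
                "only the uniform-on-sd variance prior family is implemented"
            )


@dataclass
class ModelSpec:
    """A count dataset bound to contiguous indices and a model variant.

    Index maps send stratum labels to 0..S-1, observer-route labels to
    0..J-1 and years to 0..T-1 (the year axis is the contiguous span of
    the data, so unobserved interior years still carry a year effect,
    linked through the random walk). The budworm variant requires a
    covariate table covering every count row; the naive variant forbids
    one.
    """

    variant: str
    counts: pd.DataFrame
    covariates: CovariateTable | None
    priors: PriorConfig

    strata: np.ndarray = field(init=False)
    years: np.ndarray = field(init=False)
    obsroutes: np.ndarray = field(init=False)
    c: np.ndarray = field(init=False)
    i_idx: np.ndarray = field(init=False)
    j_idx: np.ndarray = field(init=False)
    t_idx: np.ndarray = field(init=False)
    x1: np.ndarray = field(init=False)
    x2: np.ndarray = field(init=False)
    i2: np.ndarray = field(init=False)
    stratum_of_obsroute: np.ndarray = field(init=False)
    route_of_obsroute: np.ndarray = field(init=False)

    @classmethod
    def build(
        cls,
        counts: pd.DataFrame,
        covariates: CovariateTable | None = None,
        variant: str = "budworm",
        priors: PriorConfig | None = None,
    ) -> "ModelSpec":
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if variant == "budworm" and covariates is None:
            raise ValueError("budworm variant requires a covariate table")
        if variant == "naive" and covariates is not None:
            raise ValueError("naive variant must not be given covariates")
        spec = cls(variant, counts.reset_index(drop=True), covariates, priors or PriorConfig())
        spec._index()
        return spec

    def _index(self) -> None:
        counts = self.counts
        for col in ("stratum", "route", "obsroute", "year", "count", "first_year"):
            if col not in counts.columns:
                raise ValueError(f"count table missing column {col!r}")
        self.strata = np.sort(counts["stratum"].unique())
        self.obsroutes = np.sort(counts["obsroute"].unique())
        y0, y1 = int(counts["year"].min()), int(counts["year"].max())
        self.years = np.arange(y0, y1 + 1)

        s_map = {s: k for k, s in enumerate(self.strata)}
        j_map = {j: k for k, j in enumerate(self.obsroutes)}
        self.c = counts["count"].to_numpy(dtype=np.int64)
        if (self.c < 0).any():
            raise ValueError("counts must be nonnegative")
        self.i_idx = counts["stratum"].map(s_map).to_numpy(dtype=np.int64)
        self.j_idx = counts["obsroute"].map(j_map).to_numpy(dtype=np.int64)
        self.t_idx = counts["year"].to_numpy(dtype=np.int64) - y0
        self.i2 = counts["first_year"].to_numpy(dtype=np.float64)

        per_obs = counts.drop_duplicates("obsroute").set_index("obsroute")
        self.stratum_of_obsroute = (
            per_obs.loc[self.obsroutes, "stratum"].map(s_map).to_numpy(dtype=np.int64)
        )
        self.route_of_obsroute = per_obs.loc[self.obsroutes, "route"].to_numpy()

        if self.variant == "budworm":
            merged = counts.merge(
                self.covariates.route_year,
                on=["stratum", "route", "year"],
                how="left",
                validate="m:1",
            ).merge(
                self.covariates.stratum_year,
                on=["stratum", "year"],
                how="left",
                validate="m:1",
            )
            if merged[["b1", "b2", "I1"]].isna().any().any():
                raise ValueError("covariate table does not cover every count row")
            self.x1 = merged["b1"].to_numpy(dtype=np.float64)
            self.x2 = (merged["I1"] * merged["b2"]).to_numpy(dtype=np.float64)
        else:
            self.x1 = np.zeros(len(counts))
            self.x2 = np.zeros(len(counts))

    @property
    def n_strata(self) -> int:
        return self.strata.size

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_obsroutes(self) -> int:
        return self.obsroutes.size

    @property
    def n_obs(self) -> int:
        return self.c.size


def log_mean(params: dict, record: dict, variant: str = "budworm") -> float:
    """Log Poisson mean for one count record under one parameter draw.

    ``params`` holds scalars gamma, omega, eps and (budworm) beta1, beta2,
    zeta; ``record`` holds b1, b2, I1, I2. Missing entries default to 0.
    """
    eta = (
        params.get("gamma", 0.0)
        + params.get("omega", 0.0)
        + params.get("zeta", 0.0) * record.get("I2", 0.0)
        + params.get("eps", 0.0)
    )
    if variant == "budworm":
        eta += params.get("beta1", 0.0) * record.get("b1", 0.0)
        eta += params.get("beta2", 0.0) * record.get("I1", 0.0) * record.get("b2", 0.0)
    return float(eta)


def linear_predictor(point: dict, spec: ModelSpec) -> np.ndarray:
    """Vector of log-means for every count row of ``spec`` at ``point``."""
    gamma = np.asarray(point["gamma"], dtype=float)
    eta = (
        gamma[spec.i_idx, spec.t_idx]
        + np.asarray(point["omega"], dtype=float)[spec.j_idx]
        + float(point.get("zeta", 0.0)) * spec.i2
        + np.asarray(point["eps"], dtype=float)
    )
    if spec.variant == "budworm":
        eta = (
            eta
            + np.asarray(point["beta1"], dtype=float)[spec.i_idx] * spec.x1
            + np.asarray(point["beta2"], dtype=float)[spec.i_idx] * spec.x2
        )
    return eta


def _normal_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def log_posterior(point: dict, spec: ModelSpec) -> float:
    """Unnormalised log posterior density at ``point``.

    Poisson log-likelihood plus every random-effect and prior log-density.
    Points with a nonpositive SD, or an SD outside the uniform prior's
    support, score -inf.
    """
    pr = spec.priors
    sd_names = ["sigma_lambda", "sigma_omega", "sigma_eps"]
    if spec.variant == "budworm":
        sd_names += ["sigma_B1", "sigma_B2"]
    for name in sd_names:
        sd = float(point[name])
        if not 0.0 < sd <= pr.sd_upper:
            return -np.inf

    eta = linear_predictor(point, spec)
    lp = float(np.sum(spec.c * eta - np.exp(eta) - gammaln(spec.c + 1)))

    gamma = np.asarray(point["gamma"], dtype=float)
    v_lam = float(point["sigma_lambda"]) ** 2
    lp += float(np.sum(_normal_logpdf(gamma[:, 0], 0.0, v_lam * pr.gamma1_variance_inflation)))
    if gamma.shape[1] > 1:
        lp += float(np.sum(_normal_logpdf(gamma[:, 1:], gamma[:, :-1], v_lam)))

    lp += float(np.sum(_normal_logpdf(point["omega"], 0.0, float(point["sigma_omega"]) ** 2)))
    lp += float(np.sum(_normal_logpdf(point["eps"], 0.0, float(point["sigma_eps"]) ** 2)))
    lp += float(_normal_logpdf(point.get("zeta", 0.0), 0.0, pr.sd_zeta**2))

    if spec.variant == "budworm":
        lp += float(
            np.sum(_normal_logpdf(point["beta1"], point["B1"], float(point["sigma_B1"]) ** 2))
        )
        lp += float(
            np.sum(_normal_logpdf(point["beta2"], point["B2"], float(point["sigma_B2"]) ** 2))
        )
        lp += float(_normal_logpdf(point["B1"], 0.0, pr.sd_B1**2))
        lp += float(_normal_logpdf(point["B2"], 0.0, pr.sd_B2**2))
    return lp


@dataclass(frozen=True)
class PercentChange:
    """Percent-abundance scale summary of a log-scale effect: exp(beta)*100."""

    mean: float
    q2_5: float
    q97_5: float


def percent_change(beta_draws) -> PercentChange:
    """Summarise log-scale effect draws on the percent-change scale.

    Each draw beta maps to exp(beta)*100, so 100 means no change and 300
    means a threefold (""300%"") abundance level under full defoliation.
    Returns the mean and the 2.5/97.5 percentiles of the transformed draws.
    """
    pct = np.exp(np.atleast_1d(np.asarray(beta_draws, dtype=float))) * 100.0
    lo, hi = np.percentile(pct, [2.5, 97.5])
    return PercentChange(mean=float(pct.mean()), q2_5=float(lo), q97_5=float(hi))
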