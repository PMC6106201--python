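"""Predicted per-stratum population trajectories from posterior draws.

For each posterior draw, the predicted mean count in stratum i and year
t averages the exponentiated linear predictor over the observer-route
combinations of the stratum (without the observation-level effect, but
with the lognormal mean correction 0.5*sigma_eps^2 inside the
exponential), and scales by the occupancy proportion z_i:

    N^b_{i,t} = z_i/r_i * sum_j exp(gamma_{i,t} + beta1_i b1_{i,j,t}
                + beta2_i I1(t) b2_{i,t} + omega_j + 0.5 sigma_eps^2)

The no-budworm trajectory N^0 drops both defoliation terms from the same
draws (what the trajectory would have been without the outbreak); the
naive trajectory N^n applies the same formula to an independently fitted
model that never saw the defoliation predictors. Each route contributes
its own year-specific b1 value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import InclusionReport
from .model import ModelSpec
from .sampler import PosteriorDraws

__all__ = ["TrajectorySet", "trajectory", "summarise", "budworm_effect_ratio"]

WHICH = ("budworm", "no_budworm", "naive")
_CHUNK = 256


@dataclass
class TrajectorySet:
    """Draws of one trajectory variant: array (draw, stratum, year)."""

    which: str
    draws: np.ndarray
    strata: list
    years: list
    z: np.ndarray
    r: np.ndarray

    def summary(self) -> pd.DataFrame:
        return summarise(self)


def _z_vector(spec: ModelSpec, report: InclusionReport | None) -> np.ndarray:
    if report is None:
        return np.ones(spec.n_strata)
    z = np.array([report.z_by_stratum.get(s, 1.0) for s in spec.strata], dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("z_by_stratum values must lie in [0, 1]")
    return z


def _b1_matrix(spec: ModelSpec) -> np.ndarray:
    """b1 per (obsroute, year): each observer-route uses its route's series."""
    ry = spec.covariates.route_year
    pivot = ry.pivot_table(index="route", columns="year", values="b1")
    try:
        pivot = pivot.loc[spec.route_of_obsroute, spec.years]
    except KeyError as err:
        raise ValueError("covariate table does not cover every route-year") from err
    mat = pivot.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("covariate table does not cover every route-year")
    return mat


def _b2_matrix(spec: ModelSpec) -> np.ndarray:
    """I1*b2 per (stratum, year)."""
    sy = spec.covariates.stratum_year.copy()
    sy["x2"] = sy["I1"] * sy["b2"]
    pivot = sy.pivot_table(index="stratum", columns="year", values="x2")
    pivot = pivot.reindex(index=spec.strata, columns=spec.years)
    mat = pivot.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("stratum-year covariates do not cover every model year")
    return mat


def trajectory(
    draws: PosteriorDraws,
    spec: ModelSpec,
    report: InclusionReport | None = None,
    which: str = "budworm",
) -> TrajectorySet:
    """Compute one trajectory variant from posterior draws.

    ``which='budworm'`` and ``'no_budworm'`` need draws from the budworm
    fit; ``'naive'`` needs draws from a naive fit (requesting it with
    budworm draws is a usage error). ``spec`` supplies the index maps and,
    for the budworm trajectory, the defoliation covariates; ``report``
    supplies z_i (defaults to 1 for every stratum when omitted).
    """
    if which not in WHICH:
        raise ValueError(f"which must be one of {WHICH}")
    if which == "naive" and draws.variant != "naive":
        raise ValueError("the naive trajectory requires draws from a naive fit")
    if which != "naive" and draws.variant != "budworm":
        raise ValueError(f"the {which} trajectory requires draws from the budworm fit")
    for needed in ("gamma", "omega", "sigma_eps"):
        if needed not in draws.posterior:
            raise ValueError(f"{needed!r} draws are required; add it to the monitor list")

    S, T = spec.n_strata, spec.n_years
    z = _z_vector(spec, report)
    j_strat = spec.stratum_of_obsroute
    r = np.bincount(j_strat, minlength=S).astype(float)
    if np.any(r == 0):
        raise ValueError("every stratum needs at least one observer-route combination")

    gamma = draws.stacked("gamma")
    omega = draws.stacked("omega")
    sig2 = draws.stacked("sigma_eps") ** 2
    nd = gamma.shape[0]

    use_beta = which == "budworm"
    if use_beta:
        beta1 = draws.stacked("beta1")
        beta2 = draws.stacked("beta2")
        b1 = _b1_matrix(spec)
        x2 = _b2_matrix(spec)

    out = np.empty((nd, S, T))
    for lo in range(0, nd, _CHUNK):
        hi = min(lo + _CHUNK, nd)
        g = gamma[lo:hi]
        om = omega[lo:hi]
        s2 = sig2[lo:hi]
        for i in range(S):
            cols = np.flatnonzero(j_strat == i)
            w = om[:, cols]
            if use_beta:
                inner = np.exp(
                    w[:, :, None] + beta1[lo:hi, i, None, None] * b1[None, cols, :]
                ).sum(axis=1)
                outer = g[:, i, :] + beta2[lo:hi, i, None] * x2[None, i, :]
            else:
                inner = np.exp(w).sum(axis=1)[:, None]
                outer = g[:, i, :]
            out[lo:hi, i, :] = (z[i] / r[i]) * np.exp(outer + 0.5 * s2[:, None]) * inner

    return TrajectorySet(
        which=which,
        draws=out,
        strata=list(spec.strata),
        years=list(spec.years),
        z=z,
        r=r,
    )


def summarise(traj: TrajectorySet | np.ndarray) -> pd.DataFrame:
    """Posterior mean and central 95% band per stratum-year.

    Band endpoints are the empirical 2.5/97.5 percentiles across draws
    using linear interpolation between order statistics.
    """
    if isinstance(traj, TrajectorySet):
        arr, strata, years, which = traj.draws, traj.strata, traj.years, traj.which
    else:
        arr = np.asarray(traj, dtype=float)
        strata = list(range(1, arr.shape[1] + 1))
        years = list(range(1, arr.shape[2] + 1))
        which = None
    if arr.shape[0] < 1:
        raise ValueError("need at least one draw")
    mean = arr.mean(axis=0)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    S, T = mean.shape
    frame = pd.DataFrame(
        {
            "stratum": np.repeat(strata, T),
            "year": np.tile(years, S),
            "mean": mean.ravel(),
            "q2_5": lo.ravel(),
            "q97_5": hi.ravel(),
        }
    )
    if which is not None:
        frame.insert(0, "which", which)
    return frame


def budworm_effect_ratio(traj_b: TrajectorySet, traj_0: TrajectorySet) -> TrajectorySet:
    """Within-draw posterior ratio N^b / N^0 per stratum-year."""
    if traj_b.draws.shape != traj_0.draws.shape:
        raise ValueError("trajectory draw sets are not matched")
    return TrajectorySet(
        which="ratio",
        draws=traj_b.draws / traj_0.draws,
        strata=traj_b.strata,
        years=traj_b.years,
        z=traj_b.z,
        r=traj_b.r,
    )


def plot_trajectories(
    summaries: dict,
    stratum_year: pd.DataFrame | None = None,
    path=None,
):
    """Per-stratum trajectory panels with credible bands.

    ``summaries`` maps a variant label to a summary frame from
    :func:`summarise`; an optional stratum-year covariate frame overlays
    the defoliation series on a secondary axis. Returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = next(iter(summaries.values()))
    strata = sorted(first["stratum"].unique())
    ncol = min(3, len(strata))
    nrow = -(-len(strata) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    colors = {"budworm": "tab:green", "no_budworm": "tab:orange", "naive": "tab:blue"}
    for ax, stratum in zip(axes.ravel(), strata):
        for label, frame in summaries.items():
            sub = frame[frame["stratum"] == stratum]
            color = colors.get(label)
            ax.plot(sub["year"], sub["mean"], label=label, color=color)
            ax.fill_between(sub["year"], sub["q2_5"], sub["q97_5"], alpha=0.2, color=color)
        if stratum_year is not None:
            twin = ax.twinx()
            sub = stratum_year[stratum_year["stratum"] == stratum]
            twin.plot(sub["year"], sub["b2_raw"], color="gray", ls="-", lw=0.8)
            twin.plot(sub["year"], sub["b2"], color="gray", ls="--", lw=0.8)
            twin.set_ylim(0, 1)
        ax.set_title(f"stratum {stratum}")
    axes.ravel()[0].legend(fontsize=8)
    for ax in axes.ravel()[len(strata):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
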