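"""Metropolis-within-Gibbs sampler for the hierarchical count model.

The latent space is large (one overdispersion effect per observation)
but the full conditionals factorise cheaply: given everything else, the
eps are mutually independent, as are the omega, the stratum slopes, and
the year effects of equal parity within each stratum chain. Each such
block is updated with vectorised normal random-walk Metropolis steps
whose per-site scales adapt toward a 0.44 acceptance rate during burn-in
only (adaptation is frozen afterwards, preserving detailed balance).
Hyper-means (B1, B2) and all variances have conjugate conditionals under
the normal hyperdistributions and uniform-on-SD priors, and are Gibbs
sampled (the variance conditional is inverse-gamma truncated by the
prior's upper bound).

Chains run sequentially from independent named seed streams; with fixed
settings and seed the draws are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import invgamma

from ._rng import stream
from .model import ModelSpec

__all__ = ["SamplerSettings", "PosteriorDraws", "fit"]

_TARGET_ACCEPT = 0.44

HYPER_NAMES = ("B1", "B2", "sigma_B1", "sigma_B2", "sigma_lambda", "sigma_omega", "sigma_eps", "zeta")
DEFAULT_MONITOR = HYPER_NAMES + ("beta1", "beta2", "gamma", "omega")


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``iterations`` is the total per chain, of which the first ``burn_in``
    are discarded (and used for proposal adaptation); kept draws are
    thinned by ``thin``. ``monitor`` names the parameters stored;
    observation-level eps draws are stored only when ``store_eps`` is set,
    so storage scales with the monitored set rather than the model size.
    """

    chains: int = 2
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0
    monitor: tuple = DEFAULT_MONITOR
    store_eps: bool = False
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """MCMC output with chain/draw structure.

    ``posterior`` maps parameter name to an array whose leading axes are
    (chain, draw); SDs are stored on the SD (not variance) scale.
    ``coords`` carries the stratum/year/observer-route labels so draws can
    be related back to the data.
    """

    variant: str
    posterior: dict
    coords: dict
    diagnostics: dict
    settings: SamplerSettings

    def stacked(self, name: str) -> np.ndarray:
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior=self.posterior)

    def hyper_summary(self) -> dict:
        out = {}
        for name in HYPER_NAMES:
            if name in self.posterior:
                flat = self.stacked(name)
                lo, hi = np.percentile(flat, [2.5, 97.5])
                out[name] = {"mean": float(flat.mean()), "q2_5": float(lo), "q97_5": float(hi)}
        return out


def _draw_variance(rng, n_terms, ssq, sd_upper):
    """Sample sigma^2 from its conditional: InvGamma((n-1)/2, ssq/2) on (0, sd_upper^2]."""
    a = (n_terms - 1) / 2.0
    b = max(ssq / 2.0, 1e-300)
    if a <= 0:
        return (sd_upper * rng.random()) ** 2
    cap = sd_upper**2
    for _ in range(50):
        g = rng.gamma(a)
        if g > 0:
            v = b / g
            if v <= cap:
                return v
    # truncation binds; invert the CDF on the truncated region
    u = rng.random() * invgamma.cdf(cap, a, scale=b)
    return float(invgamma.ppf(max(u, 1e-12), a, scale=b))


class _Chain:
    """State and update kernels for one MCMC chain."""

    def __init__(self, spec: ModelSpec, settings: SamplerSettings, fixed: dict, rng):
        self.spec = spec
        self.settings = settings
        self.fixed = fixed
        self.rng = rng
        self.budworm = spec.variant == "budworm"

        S, T, J, N = spec.n_strata, spec.n_years, spec.n_obsroutes, spec.n_obs
        self.S, self.T, self.J, self.N = S, T, J, N
        self.c = spec.c.astype(np.float64)
        self.cell = spec.i_idx * T + spec.t_idx
        self.n_cell = np.bincount(self.cell, minlength=S * T).reshape(S, T)
        self.c_cell = np.bincount(self.cell, weights=self.c, minlength=S * T).reshape(S, T)
        self.c_j = np.bincount(spec.j_idx, weights=self.c, minlength=J)
        self.cx1_i = np.bincount(spec.i_idx, weights=self.c * spec.x1, minlength=S)
        self.cx2_i = np.bincount(spec.i_idx, weights=self.c * spec.x2, minlength=S)
        self.i2_mask = spec.i2 > 0
        self.cI2 = float((self.c * spec.i2).sum())
        self.infl = spec.priors.gamma1_variance_inflation
        self.sd_upper = spec.priors.sd_upper

        self._init_state()
        self._init_scales()
        self.eta = self._full_eta()
        self.accept_sums: dict = {}
        self.accept_n: dict = {}

    # -- initialisation -------------------------------------------------
    def _init_state(self) -> None:
        S, T, J, N = self.S, self.T, self.J, self.N
        rng, fixed = self.rng, self.fixed

        with np.errstate(divide="ignore", invalid="ignore"):
            cell_mean = np.where(self.n_cell > 0, self.c_cell / np.maximum(self.n_cell, 1), np.nan)
        stratum_mean = np.nanmean(np.where(self.n_cell > 0, cell_mean, np.nan), axis=1)
        stratum_mean = np.nan_to_num(stratum_mean, nan=0.0)
        cell_mean = np.where(np.isnan(cell_mean), stratum_mean[:, None], cell_mean)
        gamma0 = np.log(cell_mean + 0.5)

        def take(name, default):
            if name in fixed:
                return np.broadcast_to(np.asarray(fixed[name], dtype=float), np.shape(default)).copy() if np.ndim(default) else float(fixed[name])
            return default

        self.gamma = np.asarray(take("gamma", gamma0 + 0.1 * rng.standard_normal((S, T))))
        self.omega = np.asarray(take("omega", 0.05 * rng.standard_normal(J)))
        self.eps = np.asarray(take("eps", 0.05 * rng.standard_normal(N)))
        self.zeta = float(take("zeta", 0.05 * rng.standard_normal()))
        self.v_lam = float(take("sigma_lambda", 0.5)) ** 2 if "sigma_lambda" in fixed else 0.25
        self.v_om = float(take("sigma_omega", 0.5)) ** 2 if "sigma_omega" in fixed else 0.25
        self.v_eps = float(take("sigma_eps", 0.5)) ** 2 if "sigma_eps" in fixed else 0.25
        if self.budworm:
            self.beta1 = np.asarray(take("beta1", 0.05 * rng.standard_normal(self.S)))
            self.beta2 = np.asarray(take("beta2", 0.05 * rng.standard_normal(self.S)))
            self.B1 = float(take("B1", 0.0))
            self.B2 = float(take("B2", 0.0))
            self.v_B1 = float(fixed["sigma_B1"]) ** 2 if "sigma_B1" in fixed else 0.25
            self.v_B2 = float(fixed["sigma_B2"]) ** 2 if "sigma_B2" in fixed else 0.25

    def _init_scales(self) -> None:
        self.l_eps = np.full(self.N, np.log(0.5))
        self.l_om = np.full(self.J, np.log(0.5))
        self.l_gam = np.full((self.S, self.T), np.log(0.5))
        self.l_z = np.log(0.2)
        if self.budworm:
            self.l_b1 = np.full(self.S, np.log(0.2))
            self.l_b2 = np.full(self.S, np.log(0.2))

    def _full_eta(self) -> np.ndarray:
        spec = self.spec
        eta = (
            self.gamma.ravel()[self.cell]
            + self.omega[spec.j_idx]
            + self.zeta * spec.i2
            + self.eps
        )
        if self.budworm:
            eta = eta + self.beta1[spec.i_idx] * spec.x1 + self.beta2[spec.i_idx] * spec.x2
        return eta

    # -- bookkeeping ----------------------------------------------------
    def _record(self, name: str, acc, adapt_rate: float | None, scales=None) -> None:
        rate = float(np.mean(acc))
        self.accept_sums[name] = self.accept_sums.get(name, 0.0) + rate
        self.accept_n[name] = self.accept_n.get(name, 0) + 1
        if adapt_rate is not None and scales is not None:
            scales += adapt_rate * (np.asarray(acc, dtype=float) - _TARGET_ACCEPT)

    # -- Metropolis blocks ----------------------------------------------
    def update_eps(self, adapt) -> None:
        if "eps" in self.fixed:
            return
        rng = self.rng
        d = np.exp(self.l_eps) * rng.standard_normal(self.N)
        prop = self.eps + d
        delta = (
            self.c * d
            - np.exp(self.eta) * np.expm1(d)
            + (self.eps**2 - prop**2) / (2.0 * self.v_eps)
        )
        acc = np.log(rng.random(self.N)) < delta
        self.eps[acc] = prop[acc]
        self.eta[acc] += d[acc]
        self._record("eps", acc, adapt, self.l_eps)

    def update_omega(self, adapt) -> None:
        if "omega" in self.fixed:
            return
        rng, spec = self.rng, self.spec
        ee_j = np.bincount(spec.j_idx, weights=np.exp(self.eta), minlength=self.J)
        d = np.exp(self.l_om) * rng.standard_normal(self.J)
        prop = self.omega + d
        delta = self.c_j * d - ee_j * np.expm1(d) + (self.omega**2 - prop**2) / (2.0 * self.v_om)
        acc = np.log(rng.random(self.J)) < delta
        self.omega[acc] = prop[acc]
        step = np.where(acc, d, 0.0)
        self.eta += step[spec.j_idx]
        self._record("omega", acc, adapt, self.l_om)

    def update_gamma(self, adapt) -> None:
        if "gamma" in self.fixed:
            return
        rng = self.rng
        S, T = self.S, self.T
        ee_cell = np.bincount(self.cell, weights=np.exp(self.eta), minlength=S * T).reshape(S, T)
        v, K = self.v_lam, self.infl
        acc_all = np.zeros((S, T), dtype=bool)
        for parity in (0, 1):
            if parity >= T:
                break
            sel = np.zeros(T, dtype=bool)
            sel[parity::2] = True
            d = np.zeros((S, T))
            d[:, sel] = np.exp(self.l_gam[:, sel]) * rng.standard_normal((S, int(sel.sum())))
            g, gn = self.gamma, self.gamma + d

            lik = self.c_cell * d - ee_cell * np.expm1(d)
            left = np.empty((S, T))
            left[:, 0] = (g[:, 0] ** 2 - gn[:, 0] ** 2) / (2.0 * v * K)
            if T > 1:
                left[:, 1:] = ((g[:, 1:] - g[:, :-1]) ** 2 - (gn[:, 1:] - g[:, :-1]) ** 2) / (2.0 * v)
            right = np.zeros((S, T))
            if T > 1:
                right[:, :-1] = ((g[:, 1:] - g[:, :-1]) ** 2 - (g[:, 1:] - gn[:, :-1]) ** 2) / (2.0 * v)
            delta = lik + left + right

            acc = (np.log(rng.random((S, T))) < delta) & sel[None, :]
            step = np.where(acc, d, 0.0)
            self.gamma = self.gamma + step
            self.eta += step.ravel()[self.cell]
            acc_all |= acc
            # adapting with stale ee_cell for the second parity is harmless:
            # those cells' eta never changed in the first pass
        self._record("gamma", acc_all, adapt, self.l_gam)

    def _update_beta(self, which: str, adapt) -> None:
        if which in self.fixed:
            return
        rng, spec = self.rng, self.spec
        if which == "beta1":
            beta, x, csum, B, vB, lsc = self.beta1, spec.x1, self.cx1_i, self.B1, self.v_B1, self.l_b1
        else:
            beta, x, csum, B, vB, lsc = self.beta2, spec.x2, self.cx2_i, self.B2, self.v_B2, self.l_b2
        d = np.exp(lsc) * rng.standard_normal(self.S)
        dx = d[spec.i_idx] * x
        contrib = np.bincount(spec.i_idx, weights=np.exp(self.eta) * np.expm1(dx), minlength=self.S)
        prop = beta + d
        delta = d * csum - contrib + ((beta - B) ** 2 - (prop - B) ** 2) / (2.0 * vB)
        acc = np.log(rng.random(self.S)) < delta
        beta[acc] = prop[acc]
        step = np.where(acc, d, 0.0)
        self.eta += step[spec.i_idx] * x
        self._record(which, acc, adapt, lsc)

    def update_zeta(self, adapt) -> None:
        if "zeta" in self.fixed:
            return
        rng, spec = self.rng, self.spec
        d = float(np.exp(self.l_z) * rng.standard_normal())
        prop = self.zeta + d
        ee = float(np.exp(self.eta[self.i2_mask]).sum())
        delta = (
            d * self.cI2
            - ee * np.expm1(d)
            + (self.zeta**2 - prop**2) / (2.0 * spec.priors.sd_zeta**2)
        )
        acc = np.log(rng.random()) < delta
        if acc:
            self.zeta = prop
            self.eta[self.i2_mask] += d
        if adapt is not None:
            self.l_z += adapt * (float(acc) - _TARGET_ACCEPT)
        self._record("zeta", acc, None)

    # -- Gibbs blocks ----------------------------------------------------
    def update_hypers(self) -> None:
        rng = self.rng
        if self.budworm:
            for which in ("1", "2"):
                beta = self.beta1 if which == "1" else self.beta2
                vB = self.v_B1 if which == "1" else self.v_B2
                sdB = self.spec.priors.sd_B1 if which == "1" else self.spec.priors.sd_B2
                if f"B{which}" not in self.fixed:
                    prec = self.S / vB + 1.0 / sdB**2
                    mean = beta.sum() / vB / prec
                    val = float(rng.normal(mean, 1.0 / np.sqrt(prec)))
                    if which == "1":
                        self.B1 = val
                    else:
                        self.B2 = val
                if f"sigma_B{which}" not in self.fixed:
                    B = self.B1 if which == "1" else self.B2
                    v = _draw_variance(rng, self.S, float(((beta - B) ** 2).sum()), self.sd_upper)
                    if which == "1":
                        self.v_B1 = v
                    else:
                        self.v_B2 = v
        if "sigma_lambda" not in self.fixed:
            ssq = float((self.gamma[:, 0] ** 2).sum() / self.infl)
            if self.T > 1:
                ssq += float(((self.gamma[:, 1:] - self.gamma[:, :-1]) ** 2).sum())
            self.v_lam = _draw_variance(rng, self.S * self.T, ssq, self.sd_upper)
        if "sigma_omega" not in self.fixed:
            self.v_om = _draw_variance(rng, self.J, float((self.omega**2).sum()), self.sd_upper)
        if "sigma_eps" not in self.fixed:
            self.v_eps = _draw_variance(rng, self.N, float((self.eps**2).sum()), self.sd_upper)

    # -- main loop --------------------------------------------------------
    def current(self, name: str):
        scalars = {
            "B1": lambda: self.B1,
            "B2": lambda: self.B2,
            "zeta": lambda: self.zeta,
            "sigma_B1": lambda: np.sqrt(self.v_B1),
            "sigma_B2": lambda: np.sqrt(self.v_B2),
            "sigma_lambda": lambda: np.sqrt(self.v_lam),
            "sigma_omega": lambda: np.sqrt(self.v_om),
            "sigma_eps": lambda: np.sqrt(self.v_eps),
        }
        if name in scalars:
            return scalars[name]()
        return getattr(self, name)

    def run(self, monitor: tuple) -> dict:
        settings = self.settings
        kept = settings.n_kept
        store: dict = {}
        for name in monitor:
            val = np.asarray(self.current(name))
            store[name] = np.empty((kept,) + val.shape)

        k = 0
        for it in range(settings.iterations):
            adapt = min(0.25, 4.0 / np.sqrt(it + 1.0)) if it < settings.burn_in else None
            self.update_gamma(adapt)
            if self.budworm:
                self._update_beta("beta1", adapt)
                self._update_beta("beta2", adapt)
            self.update_omega(adapt)
            self.update_zeta(adapt)
            self.update_eps(adapt)
            self.update_hypers()
            if it == settings.burn_in - 1:
                # reset acceptance accounting so reported rates are post-adaptation
                self.accept_sums, self.accept_n = {}, {}
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                for name in monitor:
                    store[name][k] = self.current(name)
                k += 1
        return store


def fit(
    spec: ModelSpec,
    settings: SamplerSettings | None = None,
    fixed: dict | None = None,
) -> PosteriorDraws:
    """Draw posterior samples for ``spec``; returns draws plus diagnostics.

    ``fixed`` clamps named parameters at given values (their updates are
    skipped), which turns off parts of the model — useful for reduced-model
    checks. Diagnostics report split-Rhat and bulk ESS for the monitored
    scalar parameters and mean post-burn-in acceptance rates per block; a
    warning is emitted when any Rhat exceeds the configured threshold.
    """
    settings = settings or SamplerSettings()
    fixed = dict(fixed or {})

    monitor = [m for m in settings.monitor]
    if spec.variant == "naive":
        monitor = [m for m in monitor if m not in ("B1", "B2", "sigma_B1", "sigma_B2", "beta1", "beta2")]
    if settings.store_eps and "eps" not in monitor:
        monitor.append("eps")
    monitor = tuple(monitor)

    chain_stores = []
    acc_rates: dict = {}
    for k in range(settings.chains):
        rng = stream(settings.seed, "fit", spec.variant, k)
        chain = _Chain(spec, settings, fixed, rng)
        chain_stores.append(chain.run(monitor))
        for name, total in chain.accept_sums.items():
            acc_rates.setdefault(name, []).append(total / max(chain.accept_n[name], 1))

    posterior = {
        name: np.stack([cs[name] for cs in chain_stores]) for name in monitor
    }
    coords = {
        "strata": spec.strata.tolist(),
        "years": spec.years.tolist(),
        "obsroutes": spec.obsroutes.tolist(),
    }

    diagnostics = _diagnostics(posterior, acc_rates, fixed, settings)
    return PosteriorDraws(spec.variant, posterior, coords, diagnostics, settings)


def _diagnostics(posterior, acc_rates, fixed, settings) -> dict:
    import arviz as az

    scalars = {
        name: posterior[name]
        for name in HYPER_NAMES
        if name in posterior and name not in fixed
    }
    rhat: dict = {}
    ess: dict = {}
    if scalars and settings.n_kept >= 4:
        ds = az.from_dict(posterior=scalars)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(ds)
            e = az.ess(ds)
        rhat = {k: float(r[k].values) for k in scalars}
        ess = {k: float(e[k].values) for k in scalars}
        bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > settings.rhat_threshold}
        if bad:
            warnings.warn(
                "possible non-convergence (Rhat > "
                f"{settings.rhat_threshold}): {sorted(bad.items())}"
            )
    return {
        "rhat": rhat,
        "ess_bulk": ess,
        "acceptance": {k: float(np.mean(v)) for k, v in acc_rates.items()},
    }
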