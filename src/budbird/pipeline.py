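"""End-to-end pipeline: simulate/load -> filter -> fit -> trajectories -> report.

A run writes a self-contained directory: the (possibly simulated) data,
filtered counts and inclusion report, posterior draws and diagnostics
for the budworm fit (and optionally a naive fit), trajectory summaries,
and a JSON report with percent-change effect summaries. Every artifact
set is stamped with a hash of the configuration and the master seed, so
a rerun with the same configuration reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CovariateTable, build_covariate_table
from .filters import filter_routes
from .model import ModelSpec, PriorConfig, percent_change
from .sampler import PosteriorDraws, SamplerSettings, fit
from .simulate import (
    LatentTruth,
    OutbreakConfig,
    SimulationConfig,
    save_dataset,
    simulate_dataset,
)
from .trajectories import budworm_effect_ratio, summarise, trajectory

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("budbird")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one data source must be active: either ``simulation`` (with an
    optional ``outbreak`` shape) or the three CSV paths of a user-supplied
    dataset. ``seed`` is the master seed: it overrides the seeds embedded
    in the simulation and sampler settings so one integer controls the
    whole run.
    """

    simulation: SimulationConfig | None = None
    outbreak: OutbreakConfig | None = None
    counts_path: str | None = None
    route_year_path: str | None = None
    stratum_year_path: str | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    fit_naive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        synthetic = self.simulation is not None
        supplied = self.counts_path is not None
        if synthetic == supplied:
            raise ValueError("exactly one of simulation config or counts_path must be set")
        if supplied and (self.route_year_path is None or self.stratum_year_path is None):
            raise ValueError("user-supplied data needs counts, route-year and stratum-year paths")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - relabelled with the stage name
                raise PipelineError(f"stage '{name}' failed: {err}") from err
            log.info("stage %s: done", name)
            return out

        return inner

    return wrap


@_stage("data")
def _load_data(config: PipelineConfig, run_dir: Path):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        counts, cov, latent = simulate_dataset(sim, config.outbreak)
        save_dataset(run_dir / "data", counts, cov, latent)
        return counts, cov, latent
    counts = pd.read_csv(config.counts_path)
    cov = CovariateTable(
        pd.read_csv(config.route_year_path), pd.read_csv(config.stratum_year_path)
    )
    return counts, cov, None


@_stage("filter")
def _filter(counts: pd.DataFrame, run_dir: Path):
    filtered, report = filter_routes(counts)
    out = run_dir / "filtered"
    out.mkdir(parents=True, exist_ok=True)
    filtered.to_csv(out / "counts.csv", index=False)
    (out / "inclusion_report.json").write_text(report.to_json())
    return filtered, report


@_stage("fit")
def _fit(spec: ModelSpec, settings: SamplerSettings, run_dir: Path, label: str):
    draws = fit(spec, settings)
    out = run_dir / f"draws_{label}"
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "draws.npz", **draws.posterior)
    scalars = {
        k: draws.stacked(k)
        for k, v in draws.posterior.items()
        if v.ndim == 2
    }
    pd.DataFrame(scalars).to_csv(out / "hyper_draws.csv", index=False)
    (out / "diagnostics.json").write_text(json.dumps(draws.diagnostics, indent=2))
    for block, rate in draws.diagnostics["acceptance"].items():
        log.info("fit %s: acceptance[%s]=%.3f", label, block, rate)
    for name, r in draws.diagnostics["rhat"].items():
        log.info("fit %s: rhat[%s]=%.4f", label, name, r)
    return draws


@_stage("trajectories")
def _trajectories(draws_b, draws_n, spec_b, spec_n, report, run_dir: Path):
    out = run_dir / "trajectories"
    out.mkdir(parents=True, exist_ok=True)
    sets = {
        "budworm": trajectory(draws_b, spec_b, report, which="budworm"),
        "no_budworm": trajectory(draws_b, spec_b, report, which="no_budworm"),
    }
    if draws_n is not None:
        sets["naive"] = trajectory(draws_n, spec_n, report, which="naive")
    summaries = {k: summarise(v) for k, v in sets.items()}
    pd.concat(summaries.values(), ignore_index=True).to_csv(
        out / "trajectories.csv", index=False
    )
    ratio = budworm_effect_ratio(sets["budworm"], sets["no_budworm"])
    summarise(ratio).to_csv(out / "effect_ratio.csv", index=False)
    return sets, summaries, ratio


def _effect_summaries(draws: PosteriorDraws, spec: ModelSpec) -> dict:
    out = {"hyper": {}, "by_stratum": {}}
    for name in ("B1", "B2"):
        pc = percent_change(draws.stacked(name))
        out["hyper"][name] = dataclasses.asdict(pc)
    for k, name in enumerate(("beta1", "beta2")):
        arr = draws.stacked(name)
        for s_pos, stratum in enumerate(spec.strata):
            pc = percent_change(arr[:, s_pos])
            out["by_stratum"].setdefault(str(stratum), {})[name] = dataclasses.asdict(pc)
    return out


def _recovery_table(draws: PosteriorDraws, latent: LatentTruth) -> dict:
    truth = latent.truth
    mapping = {
        "B1": truth.B1,
        "B2": truth.B2,
        "sigma_B1": truth.sigma_B1,
        "sigma_B2": truth.sigma_B2,
        "sigma_lambda": truth.sigma_lambda,
        "sigma_omega": truth.sigma_omega,
        "sigma_eps": truth.sigma_eps,
        "zeta": truth.zeta,
    }
    table = {}
    for name, true_val in mapping.items():
        if name not in draws.posterior:
            continue
        flat = draws.stacked(name)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        table[name] = {
            "truth": float(true_val),
            "posterior_mean": float(flat.mean()),
            "q2_5": float(lo),
            "q97_5": float(hi),
            "covered": bool(lo <= true_val <= hi),
        }
    return table


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline into ``out_dir``; return the key results.

    The returned dict holds the fitted draws, trajectory sets and the
    report payload (also written to ``report.json``). Any stage failure
    raises :class:`PipelineError` naming the stage; artifacts written by
    earlier stages are left in place for debugging.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    counts, cov, latent = _load_data(config, run_dir)
    filtered, report = _filter(counts, run_dir)

    settings = dataclasses.replace(config.sampler, seed=config.seed)
    spec_b = ModelSpec.build(filtered, cov, variant="budworm", priors=config.priors)
    draws_b = _fit(spec_b, settings, run_dir, "budworm")

    draws_n = spec_n = None
    if config.fit_naive:
        spec_n = ModelSpec.build(filtered, None, variant="naive", priors=config.priors)
        draws_n = _fit(spec_n, settings, run_dir, "naive")

    sets, summaries, ratio = _trajectories(draws_b, draws_n, spec_b, spec_n, report, run_dir)

    payload = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_counts": int(len(filtered)),
        "effects": _effect_summaries(draws_b, spec_b),
        "diagnostics": {
            "budworm": draws_b.diagnostics,
            **({"naive": draws_n.diagnostics} if draws_n is not None else {}),
        },
        "inclusion": json.loads(report.to_json()),
    }
    if latent is not None:
        payload["recovery"] = _recovery_table(draws_b, latent)
    (run_dir / "report.json").write_text(json.dumps(payload, indent=2))

    return {
        "report": payload,
        "draws_budworm": draws_b,
        "draws_naive": draws_n,
        "spec_budworm": spec_b,
        "spec_naive": spec_n,
        "trajectories": sets,
        "trajectory_summaries": summaries,
        "effect_ratio": ratio,
        "inclusion_report": report,
        "latent": latent,
        "run_dir": run_dir,
    }
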