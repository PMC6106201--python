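"""Model densities: log-mean assembly, joint posterior, percent-change scale."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, poisson

from budbird import (
    ModelSpec,
    PriorConfig,
    build_covariate_table,
    log_mean,
    log_posterior,
    percent_change,
)


def tiny_counts(values, stratum=1, year_start=1):
    rows = []
    for k, c in enumerate(values):
        rows.append(
            {
                "stratum": stratum,
                "route": k + 1,
                "obsroute": k + 1,
                "year": year_start,
                "count": c,
                "first_year": 0,
            }
        )
    return pd.DataFrame(rows)


def zero_cov(counts, b1=0.0, b2_raw=0.0):
    ry = counts[["stratum", "route", "year"]].drop_duplicates().assign(b1=b1)
    years = sorted(counts["year"].unique())
    sy = pd.DataFrame(
        [(s, y, b2_raw) for s in counts["stratum"].unique() for y in years],
        columns=["stratum", "year", "b2_raw"],
    )
    return build_covariate_table(ry, sy, cutoff=min(years) - 1, lag_window=1)


def base_point(spec, rng=None, random=False):
    rng = rng or np.random.default_rng(0)
    S, T, J, N = spec.n_strata, spec.n_years, spec.n_obsroutes, spec.n_obs
    scale = 0.3 if random else 0.0
    point = {
        "gamma": scale * rng.standard_normal((S, T)),
        "omega": scale * rng.standard_normal(J),
        "eps": scale * rng.standard_normal(N),
        "zeta": scale * rng.standard_normal(),
        "sigma_lambda": 0.4,
        "sigma_omega": 0.5,
        "sigma_eps": 0.6,
    }
    if spec.variant == "budworm":
        point.update(
            {
                "beta1": scale * rng.standard_normal(S) + 0.5,
                "beta2": scale * rng.standard_normal(S) - 0.2,
                "B1": 0.4,
                "B2": -0.1,
                "sigma_B1": 0.3,
                "sigma_B2": 0.3,
            }
        )
    return point


class TestLogMean:
    def test_additive_identity(self):
        assert log_mean({}, {}) == 0.0

    def test_worked_example(self):
        params = {"gamma": 1.0, "beta1": 1.1}
        record = {"b1": 1.0}
        assert log_mean(params, record) == pytest.approx(2.1)

    def test_indicator_gates_regional_term(self):
        params = {"beta2": 5.0}
        assert log_mean(params, {"I1": 0, "b2": 0.9}) == 0.0
        assert log_mean(params, {"I1": 1, "b2": 0.9}) == pytest.approx(4.5)

    def test_naive_variant_ignores_covariates(self):
        params = {"gamma": 0.3, "omega": 0.1, "beta1": 9.0, "beta2": 9.0}
        record = {"b1": 1.0, "b2": 1.0, "I1": 1}
        assert log_mean(params, record, variant="naive") == pytest.approx(0.4)


class TestLogPosterior:
    def test_matches_independent_density_arithmetic(self):
        """Joint density equals a row-by-row scipy computation."""
        rng = np.random.default_rng(42)
        rows = []
        for s in (1, 2):
            for r in (1, 2):
                for y in range(1, 7):
                    rows.append(
                        {
                            "stratum": s,
                            "route": 10 * s + r,
                            "obsroute": 10 * s + r,
                            "year": y,
                            "count": int(rng.poisson(2.0)),
                            "first_year": int(y == 1),
                        }
                    )
        counts = pd.DataFrame(rows)
        ry = counts[["stratum", "route", "year"]].drop_duplicates().assign(
            b1=rng.random(24)
        )
        sy = pd.DataFrame(
            [(s, y, 0.1 * y) for s in (1, 2) for y in range(1, 7)],
            columns=["stratum", "year", "b2_raw"],
        )
        cov = build_covariate_table(ry, sy, cutoff=2, lag_window=2)
        assert cov.stratum_year["I1"].sum() > 0  # regional term active somewhere
        spec = ModelSpec.build(counts, cov, priors=PriorConfig())
        point = base_point(spec, random=True)

        merged = counts.merge(cov.merged(), on=["stratum", "route", "year"])
        expected = 0.0
        for n, row in merged.iterrows():
            i = list(spec.strata).index(row["stratum"])
            t = list(spec.years).index(row["year"])
            j = list(spec.obsroutes).index(row["obsroute"])
            eta = log_mean(
                {
                    "gamma": point["gamma"][i, t],
                    "omega": point["omega"][j],
                    "eps": point["eps"][n],
                    "zeta": point["zeta"],
                    "beta1": point["beta1"][i],
                    "beta2": point["beta2"][i],
                },
                {"b1": row["b1"], "b2": row["b2"], "I1": row["I1"], "I2": row["first_year"]},
            )
            expected += poisson.logpmf(row["count"], np.exp(eta))
        pr = spec.priors
        expected += norm.logpdf(
            point["gamma"][:, 0], 0, point["sigma_lambda"] * np.sqrt(pr.gamma1_variance_inflation)
        ).sum()
        expected += norm.logpdf(
            point["gamma"][:, 1:], point["gamma"][:, :-1], point["sigma_lambda"]
        ).sum()
        expected += norm.logpdf(point["omega"], 0, point["sigma_omega"]).sum()
        expected += norm.logpdf(point["eps"], 0, point["sigma_eps"]).sum()
        expected += norm.logpdf(point["zeta"], 0, pr.sd_zeta)
        expected += norm.logpdf(point["beta1"], point["B1"], point["sigma_B1"]).sum()
        expected += norm.logpdf(point["beta2"], point["B2"], point["sigma_B2"]).sum()
        expected += norm.logpdf(point["B1"], 0, pr.sd_B1)
        expected += norm.logpdf(point["B2"], 0, pr.sd_B2)
        assert log_posterior(point, spec) == pytest.approx(expected)

    def test_poisson_count_contributions(self):
        """c=0 at lambda=1 contributes -1; c=2 contributes -1 - log 2."""
        c0 = tiny_counts([0])
        c2 = tiny_counts([2])
        spec0 = ModelSpec.build(c0, None, variant="naive")
        spec2 = ModelSpec.build(c2, None, variant="naive")
        point = base_point(spec0)
        assert log_posterior(point, spec2) - log_posterior(point, spec0) == pytest.approx(
            -np.log(2)
        )

    def test_duplicating_records_doubles_likelihood(self):
        counts = tiny_counts([1, 4, 2])
        dup = pd.concat([counts, counts.assign(route=lambda d: d.route + 10,
                                               obsroute=lambda d: d.obsroute + 10)],
                        ignore_index=True)
        spec = ModelSpec.build(counts, None, variant="naive")
        spec_dup = ModelSpec.build(dup, None, variant="naive")
        point = base_point(spec)
        point_dup = base_point(spec_dup)
        # with all effects zero the extra rows change only likelihood + the
        # duplicated omega/eps prior terms
        lik = poisson.logpmf(counts["count"], 1.0).sum()
        extra_priors = 3 * norm.logpdf(0, 0, point["sigma_omega"]) + 3 * norm.logpdf(
            0, 0, point["sigma_eps"]
        )
        assert log_posterior(point_dup, spec_dup) - log_posterior(point, spec) == pytest.approx(
            lik + extra_priors
        )

    def test_nonpositive_variance_rejected(self):
        spec = ModelSpec.build(tiny_counts([1]), None, variant="naive")
        point = base_point(spec)
        point["sigma_eps"] = 0.0
        assert log_posterior(point, spec) == -np.inf
        point["sigma_eps"] = spec.priors.sd_upper + 1
        assert log_posterior(point, spec) == -np.inf

    def test_variant_gating_identity_with_zero_covariates(self):
        """With b1=b2=0 both variants define the same posterior over shared params."""
        counts = tiny_counts([2, 0, 3, 1])
        cov = zero_cov(counts, b1=0.0, b2_raw=0.0)
        spec_b = ModelSpec.build(counts, cov, variant="budworm")
        spec_n = ModelSpec.build(counts, None, variant="naive")
        rng = np.random.default_rng(3)
        p1 = base_point(spec_b, rng, random=True)
        p2 = base_point(spec_b, rng, random=True)
        # keep the beta block identical so its prior terms cancel
        for key in ("beta1", "beta2", "B1", "B2", "sigma_B1", "sigma_B2"):
            p2[key] = p1[key]
        shared = ("gamma", "omega", "eps", "zeta", "sigma_lambda", "sigma_omega", "sigma_eps")
        n1 = {k: p1[k] for k in shared}
        n2 = {k: p2[k] for k in shared}
        delta_b = log_posterior(p1, spec_b) - log_posterior(p2, spec_b)
        delta_n = log_posterior(n1, spec_n) - log_posterior(n2, spec_n)
        assert delta_b == pytest.approx(delta_n)

    def test_stratum_label_invariance(self, small_dataset):
        _, _, counts, cov, _ = small_dataset
        spec = ModelSpec.build(counts, cov)
        point = base_point(spec, random=True)
        lp = log_posterior(point, spec)

        relabel = {1: 30, 2: 10, 3: 20}
        counts2 = counts.assign(stratum=counts["stratum"].map(relabel))
        from budbird.covariates import CovariateTable

        cov2 = CovariateTable(
            cov.route_year.assign(stratum=cov.route_year["stratum"].map(relabel)),
            cov.stratum_year.assign(stratum=cov.stratum_year["stratum"].map(relabel)),
        )
        spec2 = ModelSpec.build(counts2, cov2)
        # sorted new labels 10,20,30 correspond to old strata 2,3,1
        perm = [1, 2, 0]
        point2 = dict(point)
        for key in ("gamma", "beta1", "beta2"):
            point2[key] = point[key][perm]
        assert log_posterior(point2, spec2) == pytest.approx(lp)


class TestModelSpecValidation:
    def test_budworm_requires_covariates(self):
        with pytest.raises(ValueError, match="requires"):
            ModelSpec.build(tiny_counts([1]), None, variant="budworm")

    def test_naive_forbids_covariates(self):
        counts = tiny_counts([1])
        with pytest.raises(ValueError, match="naive"):
            ModelSpec.build(counts, zero_cov(counts), variant="naive")

    def test_missing_covariate_rows_rejected(self):
        counts = tiny_counts([1, 2, 3])
        cov = zero_cov(counts.iloc[:2])
        with pytest.raises(ValueError, match="cover"):
            ModelSpec.build(counts, cov)


class TestPercentChange:
    def test_worked_transform(self):
        pc = percent_change(1.1)
        assert pc.mean == pytest.approx(np.exp(1.1) * 100)

    @pytest.mark.parametrize("beta,expected", [(0.0, 100.0), (np.log(2), 200.0)])
    def test_closed_forms(self, beta, expected):
        assert percent_change(beta).mean == pytest.approx(expected)

    def test_quantiles_are_2_5_and_97_5(self):
        draws = np.log(np.arange(1, 101) / 100.0)
        pc = percent_change(draws)
        assert pc.q2_5 == pytest.approx(np.percentile(np.arange(1, 101), 2.5))
        assert pc.q97_5 == pytest.approx(np.percentile(np.arange(1, 101), 97.5))
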