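"""Nested logistic model: reduction, partitioning, posteriors, flags, trends."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import opioidtraj as ot
from opioidtraj.multilevel import (
    LATENT_RESIDUAL_VARIANCE,
    NestingError,
    flag_interval,
)


def make_groups(n_regions, practices_per_region, prescribers_per_practice, patients_per_prescriber):
    rows = []
    d = 0
    for r in range(n_regions):
        for p in range(practices_per_region):
            for _ in range(prescribers_per_practice):
                for _k in range(patients_per_prescriber):
                    rows.append((f"r{r}", f"p{r}_{p}", f"d{d}"))
                d += 1
    return pd.DataFrame(rows, columns=["region", "practice", "prescriber"])


def simulate_flat(seed, n, beta, intercept=-1.7):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, len(beta))) < 0.3).astype(float)
    eta = intercept + X @ np.asarray(beta)
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


class TestFitBasics:
    def test_non_nested_ids_rejected(self):
        groups = pd.DataFrame(
            {"region": ["r0", "r0"], "practice": ["p0", "p1"], "prescriber": ["d0", "d0"]}
        )
        with pytest.raises(NestingError, match="prescriber"):
            ot.NestedLogisticRegression().fit(np.zeros((2, 1)), [0, 1], groups)

    def test_missing_hierarchy_id_rejected(self):
        groups = pd.DataFrame({"region": ["r0", None], "practice": ["p0", "p1"], "prescriber": ["d0", "d1"]})
        with pytest.raises(ValueError, match="complete hierarchy"):
            ot.NestedLogisticRegression().fit(np.zeros((2, 1)), [0, 1], groups)

    def test_sklearn_params_roundtrip(self):
        m = ot.NestedLogisticRegression(sigma_bound=3.0)
        assert m.get_params()["sigma_bound"] == 3.0
        m.set_params(sigma_bound=4.0)
        assert m.sigma_bound == 4.0

    def test_zero_variance_reduces_to_single_level_logit(self):
        """With no clustering the fit matches exact single-level ML."""
        import statsmodels.api as sm

        X, y = simulate_flat(13, 24000, [0.7, -0.4, 0.2])
        groups = make_groups(2, 3, 4, 1000)
        m = ot.NestedLogisticRegression().fit(X, y, groups)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(m.coef_, ref.params[1:], atol=1e-3)
        assert abs(m.intercept_ - ref.params[0]) < 1e-3

    def test_single_covariate_consistency(self):
        """A log-OR of ln 2 is recovered within 0.05 at n = 50,000."""
        cfg = ot.SimConfig(
            seed=5,
            n_regions=5, practices_per_region=2, prescribers_per_practice=2, patients_per_prescriber=2500,
            sigma2_region=0.0, sigma2_practice=0.0, sigma2_prescriber=0.0,
            beta={"gabapentinoid": math.log(2)},
        )
        _, truth = ot.generate_population(cfg)
        df = truth.patients
        m = ot.NestedLogisticRegression().fit(
            df[["x_gabapentinoid"]], df["latent_long_term"], df[["region_id", "practice_id", "staff_id"]]
        )
        assert abs(m.coef_[0] - math.log(2)) < 0.05

    def test_predict_proba_shapes_and_bounds(self):
        X, y = simulate_flat(1, 400, [0.5])
        groups = make_groups(2, 2, 2, 50)
        m = ot.NestedLogisticRegression().fit(X, y, groups)
        proba = m.predict_proba(X)
        assert proba.shape == (400, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_agrees_with_lme4_reference(self, tmp_path):
        """Cross-check against glmer (Laplace) on one simulated dataset."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        cfg = ot.SimConfig(
            seed=21, n_regions=4, practices_per_region=4, prescribers_per_practice=4,
            patients_per_prescriber=40, sigma2_region=0.02, sigma2_practice=0.05, sigma2_prescriber=0.3,
        )
        _, truth = ot.generate_population(cfg)
        df = truth.patients
        cols = ["x_gabapentinoid", "x_depression"]
        m = ot.NestedLogisticRegression().fit(
            df[cols], df["latent_long_term"], df[["region_id", "practice_id", "staff_id"]]
        )
        csv = tmp_path / "d.csv"
        df[cols + ["latent_long_term", "region_id", "practice_id", "staff_id"]].to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- glmer(latent_long_term ~ x_gabapentinoid + x_depression +
                           (1|region_id) + (1|practice_id) + (1|staff_id), data=d, family=binomial)
                vc <- as.data.frame(VarCorr(m))
                cat(vc$vcov[vc$grp=="staff_id"], vc$vcov[vc$grp=="practice_id"],
                    vc$vcov[vc$grp=="region_id"], fixef(m), sep="\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300, check=True
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        s2_staff, s2_prac, s2_reg, b0, b1, b2 = vals
        assert m.sigma2_prescriber_ == pytest.approx(s2_staff, abs=0.02)
        assert m.sigma2_practice_ == pytest.approx(s2_prac, abs=0.02)
        assert m.sigma2_region_ == pytest.approx(s2_reg, abs=0.02)
        assert m.intercept_ == pytest.approx(b0, abs=0.03)
        assert m.coef_[0] == pytest.approx(b1, abs=0.03)
        assert m.coef_[1] == pytest.approx(b2, abs=0.03)


class TestVariancePartition:
    def test_all_zero_gives_zero_shares(self):
        shares = ot.variance_partition(0.0, 0.0, 0.0)
        assert shares["region"] == shares["practice"] == shares["prescriber"] == 0.0
        assert shares["residual"] == 100.0

    def test_prescriber_equal_to_residual_gives_half(self):
        shares = ot.variance_partition(0.0, 0.0, LATENT_RESIDUAL_VARIANCE)
        assert shares["prescriber"] == pytest.approx(50.0)

    def test_closed_form_arithmetic(self):
        s2 = (0.0003, 0.020, 0.074)
        total = sum(s2) + LATENT_RESIDUAL_VARIANCE
        shares = ot.variance_partition(*s2)
        assert shares["region"] == pytest.approx(100 * s2[0] / total)
        assert shares["practice"] == pytest.approx(100 * s2[1] / total)
        assert shares["prescriber"] == pytest.approx(100 * s2[2] / total)

    def test_shares_sum_to_100_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s2 = rng.uniform(0, 2, 3)
            shares = ot.variance_partition(*s2)
            assert sum(shares.values()) == pytest.approx(100.0, abs=1e-12)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            ot.variance_partition(-0.1, 0, 0)

    def test_fit_exposes_partition(self):
        X, y = simulate_flat(3, 500, [0.4])
        m = ot.NestedLogisticRegression().fit(X, y, make_groups(2, 2, 5, 25))
        shares = ot.explained_variation(m)
        assert m.residual_latent_variance_ == LATENT_RESIDUAL_VARIANCE
        assert sum(shares.values()) == pytest.approx(100.0)


@pytest.fixture(scope="module")
def clustered_fit():
    cfg = ot.SimConfig(
        seed=17, n_regions=3, practices_per_region=3, prescribers_per_practice=4,
        patients_per_prescriber=60, sigma2_region=0.01, sigma2_practice=0.05, sigma2_prescriber=0.5,
    )
    _, truth = ot.generate_population(cfg)
    df = truth.patients
    m = ot.NestedLogisticRegression().fit(
        df[["x_gabapentinoid", "x_depression"]],
        df["latent_long_term"],
        df[["region_id", "practice_id", "staff_id"]],
    )
    return m, truth


class TestRandomEffectSimulation:
    def test_fixed_seed_reproducible(self, clustered_fit):
        m, _ = clustered_fit
        a = ot.simulate_random_effects(m, n_sims=200, seed=9)
        b = ot.simulate_random_effects(m, n_sims=200, seed=9)
        for level in a:
            pd.testing.assert_frame_equal(a[level], b[level])

    def test_small_n_sims_warns(self, clustered_fit):
        m, _ = clustered_fit
        with pytest.warns(UserWarning, match="small"):
            ot.simulate_random_effects(m, n_sims=50, seed=1)
        with pytest.raises(ValueError):
            ot.simulate_random_effects(m, n_sims=0, seed=1)

    def test_conditional_sd_bounded_by_prior_sd(self, clustered_fit):
        """Shrinkage: conditional spread never exceeds the level σ."""
        m, _ = clustered_fit
        for level, s2 in [
            ("region", m.sigma2_region_),
            ("practice", m.sigma2_practice_),
            ("prescriber", m.sigma2_prescriber_),
        ]:
            assert (m.random_effect_sd_[level] <= math.sqrt(s2) + 1e-8).all()

    def test_extreme_unit_has_positive_posterior(self):
        """A prescriber whose patients are all long-term sits above average."""
        rng = np.random.default_rng(4)
        groups = make_groups(2, 2, 5, 40)
        y = (rng.random(len(groups)) < 0.2).astype(float)
        y[groups["prescriber"] == "d0"] = 1.0
        m = ot.NestedLogisticRegression().fit(np.zeros((len(groups), 1)), y, groups)
        draws = ot.simulate_random_effects(m, n_sims=500, seed=2)
        assert draws["prescriber"].loc["d0"].mean() > 0


class TestSummariseAndFlag:
    @pytest.mark.parametrize(
        "interval, expected",
        [
            ((1.42, 2.26), "high"),
            ((0.53, 0.68), "low"),
            ((0.9, 1.2), "average"),
            ((1.0, 1.5), "average"),  # boundary: lower bound not above 1
        ],
    )
    def test_flag_rule(self, interval, expected):
        assert flag_interval(*interval) == expected

    def test_summary_scales_and_ranks(self, clustered_fit):
        m, _ = clustered_fit
        draws = ot.simulate_random_effects(m, n_sims=400, seed=3)
        summary = ot.summarize_and_flag(draws, m, population_reference=0.146)
        presc = summary[summary["level"] == "prescriber"].sort_values("rank")
        # OR interval is the exponentiated log-odds interval
        np.testing.assert_allclose(presc["or_lo"], np.exp(presc["lo"]))
        np.testing.assert_allclose(presc["or_hi"], np.exp(presc["hi"]))
        # ranks: 1 = highest point estimate, monotone thereafter
        assert presc["estimate"].is_monotonic_decreasing
        assert list(presc["rank"]) == list(range(1, len(presc) + 1))
        # flags consistent with the interval rule
        for row in summary.itertuples(index=False):
            assert row.flag == flag_interval(row.or_lo, row.or_hi)

    def test_false_flag_rate_under_true_null(self):
        """With no true clustering, shrinkage keeps high flags at or below nominal."""
        cfg = ot.SimConfig(
            seed=29, n_regions=3, practices_per_region=4, prescribers_per_practice=4,
            patients_per_prescriber=40, sigma2_region=0.0, sigma2_practice=0.0, sigma2_prescriber=0.0,
            beta={},
        )
        _, truth = ot.generate_population(cfg)
        df = truth.patients
        m = ot.NestedLogisticRegression().fit(
            np.zeros((len(df), 1)), df["latent_long_term"], df[["region_id", "practice_id", "staff_id"]]
        )
        draws = ot.simulate_random_effects(m, n_sims=500, seed=5)
        summary = ot.summarize_and_flag(draws, m, population_reference=0.146)
        n_units = len(summary)
        rate = (summary["flag"] == "high").mean()
        assert rate <= 0.025 + 3 * math.sqrt(0.025 * 0.975 / n_units)


class TestProportionTransform:
    def test_zero_maps_to_anchor(self):
        assert ot.effect_to_proportion(0.0, 0.146) == pytest.approx(0.146)

    def test_monotone_and_limits(self):
        us = np.linspace(-6, 6, 101)
        props = ot.effect_to_proportion(us, 0.146)
        assert np.all(np.diff(props) > 0)
        assert ot.effect_to_proportion(30.0, 0.146) > 0.999

    def test_closed_form_value(self):
        u = math.log(1.79)
        expected = expit(logit(0.146) + u)
        assert ot.effect_to_proportion(u, 0.146) == pytest.approx(expected)

    def test_bad_anchor_rejected(self):
        with pytest.raises(ValueError):
            ot.effect_to_proportion(0.0, 1.0)

    def test_marginal_transform_averages_over_covariates(self, clustered_fit):
        m, truth = clustered_fit
        X = truth.patients[["x_gabapentinoid", "x_depression"]]
        at_zero = ot.marginal_effect_to_proportion(m, X, 0.0)[0]
        expected = m.predict_proba(X)[:, 1].mean()
        assert at_zero == pytest.approx(expected)
        up, down = ot.marginal_effect_to_proportion(m, X, [1.0, -1.0])
        assert down < at_zero < up

    def test_summary_supports_marginal_scale(self, clustered_fit):
        m, truth = clustered_fit
        X = truth.patients[["x_gabapentinoid", "x_depression"]]
        draws = ot.simulate_random_effects(m, n_sims=200, seed=8)
        s = ot.summarize_and_flag(draws, m, 0.146, proportion_scale="marginal", X=X)
        assert ((s["proportion_lo"] <= s["proportion"]) & (s["proportion"] <= s["proportion_hi"])).all()
        with pytest.raises(ValueError, match="needs the covariate matrix"):
            ot.summarize_and_flag(draws, m, 0.146, proportion_scale="marginal")


class TestAnnualRates:
    def test_rate_arithmetic(self):
        rx = pd.DataFrame({"ingredient": ["codeine"] * 100, "year": [2010] * 100})
        den = pd.DataFrame({"year": [2010], "n_registered": [500_000]})
        out = ot.annual_prescription_rate(rx, den)
        assert out.loc[0, "rate_per_10000"] == pytest.approx(2.0)

    def test_absent_ingredient_year_is_zero(self):
        rx = pd.DataFrame({"ingredient": ["codeine", "morphine"], "year": [2010, 2011]})
        den = pd.DataFrame({"year": [2010, 2011], "n_registered": [1000, 1000]})
        out = ot.annual_prescription_rate(rx, den).set_index(["ingredient", "year"])
        assert out.loc[("codeine", 2011), "n_prescriptions"] == 0
        assert out.loc[("morphine", 2010), "rate_per_10000"] == 0.0

    def test_zero_denominator_rejected(self):
        rx = pd.DataFrame({"ingredient": ["codeine"], "year": [2010]})
        den = pd.DataFrame({"year": [2010], "n_registered": [0]})
        with pytest.raises(ValueError, match="denominator"):
            ot.annual_prescription_rate(rx, den)

    def test_codeine_dominates_default_mix(self, small_study):
        out = ot.annual_prescription_rate(small_study.therapy, small_study.denominators)
        by_year = out.pivot(index="year", columns="ingredient", values="rate_per_10000")
        years_with_any = by_year[by_year.sum(axis=1) > 0]
        assert (years_with_any.idxmax(axis=1) == "codeine").all()
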