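"""Twin-model likelihoods, fitting, comparisons, profiles, polychorics."""

import math

import numpy as np
import pytest

from twinchol.biometric import (
    CholeskyParameters,
    FitOptions,
    ModelFit,
    VarianceComponents,
    cholesky_from_components,
    cohort_minus2_loglik,
    compare_models,
    fit_model,
    pair_likelihood,
    polychoric_correlation,
    profile_ci,
    variance_components,
)
from twinchol.core import Zygosity
from twinchol.simulate import calibrate_thresholds, simulate_cohort

from conftest import make_pair
from test_simulate import univariate_model


def biv_params(r_a=0.5, r_c=0.0, r_e=0.2, shares1=(0.4, 0.1, 0.5),
               shares2=(0.5, 0.1, 0.4), thr1=(-0.5, 0.6), thr2=(0.0,)):
    return cholesky_from_components(shares1, thr1, shares2, thr2,
                                    r_a=r_a, r_c=r_c, r_e=r_e)


class TestPairLikelihood:
    def test_e_only_fair_orthants(self):
        params = cholesky_from_components((0.0, 0.0, 1.0), [0.0])
        pair = make_pair("F1", Zygosity.MZ, {"t": 1}, {"t": 1})
        assert pair_likelihood(params, pair, ["t"]) == pytest.approx(0.25, abs=1e-12)

    def test_perfect_heritability_mz_concordant_only(self):
        params = cholesky_from_components((1 - 1e-14, 0.0, 1e-14), [0.0])
        discordant = make_pair("F1", Zygosity.MZ, {"t": 1}, {"t": 0})
        concordant = make_pair("F2", Zygosity.MZ, {"t": 1}, {"t": 1})
        assert pair_likelihood(params, discordant, ["t"]) == pytest.approx(0.0, abs=1e-7)
        assert pair_likelihood(params, concordant, ["t"]) == pytest.approx(0.5, abs=1e-6)

    def test_bivariate_complete_pair_vs_quadrature_oracle(self):
        """4-D rectangle equals adaptive quadrature of the normal density."""
        from scipy import integrate
        from scipy.stats import multivariate_normal as scipy_mvn
        from twinchol.biometric import implied_correlation

        params = biv_params()
        pair = make_pair("F1", Zygosity.DZ, {"ed": 1, "sud": 1}, {"ed": 2, "sud": 0})
        ours = pair_likelihood(params, pair, ["ed", "sud"])
        corr = implied_correlation(params, Zygosity.DZ)
        pdf = scipy_mvn(np.zeros(4), corr).pdf
        # bounds: ed cat 1 -> (-0.5, 0.6); sud 1 -> (0, inf~8);
        # ed cat 2 -> (0.6, inf~8); sud 0 -> (-8, 0)
        ref, _ = integrate.nquad(
            lambda a, b, c, d: pdf([a, b, c, d]),
            [(-0.5, 0.6), (0.0, 8.0), (0.6, 8.0), (-8.0, 0.0)],
            opts=dict(epsabs=1e-8),
        )
        assert ours == pytest.approx(ref, abs=1e-5)

    def test_singleton_and_missing_dims(self):
        params = biv_params()
        singleton = make_pair("F1", Zygosity.MZ, {"ed": 0, "sud": 1})
        p = pair_likelihood(params, singleton, ["ed", "sud"])
        assert 0 < p < 1
        partially = make_pair("F2", Zygosity.MZ, {"ed": 0, "sud": None},
                              {"ed": None, "sud": None})
        p2 = pair_likelihood(params, partially, ["ed", "sud"])
        from scipy.stats import norm
        assert p2 == pytest.approx(norm.cdf(-0.5), abs=1e-12)

    def test_absent_trait_is_an_error(self):
        params = cholesky_from_components((0.5, 0.0, 0.5), [0.0])
        pair = make_pair("F1", Zygosity.MZ, {"other": 1}, {"other": 0})
        with pytest.raises(ValueError, match="absent"):
            pair_likelihood(params, pair, ["t"])

    @pytest.mark.parametrize("zyg", [Zygosity.MZ, Zygosity.DZ])
    def test_normalization_univariate(self, zyg):
        """Pair probabilities over all category combinations sum to one."""
        params = cholesky_from_components((0.4, 0.2, 0.4), [-0.8, 0.3, 1.1])
        total = sum(
            pair_likelihood(params, make_pair("F", zyg, {"t": i}, {"t": j}), ["t"])
            for i in range(4) for j in range(4)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("zyg", [Zygosity.MZ, Zygosity.DZ])
    def test_normalization_bivariate_4d(self, zyg):
        params = biv_params()
        total = sum(
            pair_likelihood(
                params,
                make_pair("F", zyg, {"ed": i1, "sud": j1}, {"ed": i2, "sud": j2}),
                ["ed", "sud"])
            for i1 in range(3) for j1 in range(2)
            for i2 in range(3) for j2 in range(2)
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestCohortLoglik:
    def setup_method(self):
        self.params = cholesky_from_components((0.4, 0.2, 0.4), [0.2])
        self.cohort = [
            make_pair("F1", Zygosity.MZ, {"t": 1}, {"t": 1}),
            make_pair("F2", Zygosity.DZ, {"t": 0}, {"t": 1}),
            make_pair("F3", Zygosity.DZ, {"t": 0}),
        ]

    def test_single_pair(self):
        pair = self.cohort[0]
        p = pair_likelihood(self.params, pair, ["t"])
        assert cohort_minus2_loglik(self.params, [pair], ["t"]) == pytest.approx(
            -2 * math.log(p), abs=1e-9)

    def test_duplication_doubles(self):
        one = cohort_minus2_loglik(self.params, self.cohort, ["t"])
        two = cohort_minus2_loglik(self.params, self.cohort * 2, ["t"])
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_twin_order_invariance(self):
        from twinchol.core import TwinPairRecord
        swapped = [
            TwinPairRecord(r.family_id, r.zygosity, r.twin2 or r.twin1,
                           r.twin1 if r.twin2 is not None else None)
            for r in self.cohort
        ]
        assert cohort_minus2_loglik(self.params, swapped, ["t"]) == pytest.approx(
            cohort_minus2_loglik(self.params, self.cohort, ["t"]), rel=1e-12)


class TestVarianceComponents:
    def test_no_shared_genetic_path(self):
        p = biv_params(r_a=0.0)
        assert variance_components(p).r_a == pytest.approx(0.0, abs=1e-12)

    def test_single_common_factor(self):
        p = biv_params(r_a=1.0)
        assert variance_components(p).r_a == pytest.approx(1.0, abs=1e-12)

    def test_path_arithmetic(self):
        p = CholeskyParameters(
            a11=0.6, a21=0.3, a22=0.4,
            c11=0.0, c21=0.0, c22=0.0,
            e11=0.8, e21=math.sqrt(1 - 0.09 - 0.16 - 0.0), e22=0.0,
            thresholds_trait1=np.array([0.0]),
            thresholds_trait2=np.array([0.0]),
        )
        vc = variance_components(p)
        assert vc.r_a == pytest.approx(0.3 / math.sqrt(0.09 + 0.16), abs=1e-12)
        assert vc.r_a == pytest.approx(0.6)

    def test_zero_component_correlation_undefined(self):
        p = biv_params(shares1=(0.5, 0.0, 0.5), shares2=(0.5, 0.0, 0.5), r_c=0.0)
        assert variance_components(p).r_c is None


def fake_fit(label, m2ll, nfree):
    vc = VarianceComponents(a2=(0.5,), c2=(0.0,), e2=(0.5,))
    return ModelFit(label, cholesky_from_components((0.5, 0.0, 0.5), [0.0]),
                    m2ll, nfree, 100, 0, True, vc)


class TestCompareModels:
    def test_identical_fits_aic_drops_by_two_per_df(self):
        # dropping three C paths with no fit change lowers AIC by exactly 6
        cr = compare_models(fake_fit("ACE", 1000.0, 7), fake_fit("AE", 1000.0, 4))
        assert cr.delta_chi2 == 0.0
        assert cr.delta_df == 3
        assert cr.aic_delta == pytest.approx(-6.0)

    def test_published_smoking_row_p_value(self):
        cr = compare_models(fake_fit("ACE", 1000.0, 7), fake_fit("AE", 1000.67, 4))
        assert cr.p_value == pytest.approx(0.88, abs=0.003)

    def test_same_model_twice_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            compare_models(fake_fit("ACE", 1000.0, 7), fake_fit("ACE", 1000.0, 7))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            compare_models(fake_fit("AE", 1000.0, 4), fake_fit("CE", 1001.0, 4))

    def test_submodel_fitting_better_flags_optimizer_failure(self):
        with pytest.raises(ValueError, match="optimizer failure"):
            compare_models(fake_fit("ACE", 1000.0, 7), fake_fit("AE", 999.0, 4))


class TestFitModel:
    def test_e_model_equals_closed_form_marginal_fit(self):
        """With no familial structure the likelihood factorizes: the E-model
        deviance equals the saturated marginal-frequency deviance."""
        model = univariate_model(0.5, 0.1, 0.4, thresholds=(-0.4, 0.7), seed=8,
                                 n_categories=3)
        recs = simulate_cohort(model, 150, 100)
        fit = fit_model(recs, ["trait"], "E")
        vals = [tw.phenotypes["trait"] for r in recs
                for tw in (r.twin1, r.twin2) if tw is not None]
        counts = np.bincount(vals, minlength=3)
        freqs = counts / counts.sum()
        closed = -2 * float((counts * np.log(freqs)).sum())
        assert fit.minus2_loglik == pytest.approx(closed, abs=1e-8)
        assert fit.n_free_params == 0

    def test_nesting_monotonicity(self):
        model = univariate_model(0.5, 0.15, 0.35, seed=42)
        recs = simulate_cohort(model, 300, 220)
        fits = {l: fit_model(recs, ["trait"], l, FitOptions(seed=0))
                for l in ("ACE", "AE", "CE", "E")}
        assert fits["ACE"].minus2_loglik <= fits["AE"].minus2_loglik + 1e-4
        assert fits["ACE"].minus2_loglik <= fits["CE"].minus2_loglik + 1e-4
        assert fits["AE"].minus2_loglik <= fits["E"].minus2_loglik + 1e-4
        assert fits["ACE"].n_free_params == 2

    def test_no_shared_environment_recovered(self):
        """Data generated without C: ACE lands near c2=0 and AE matches its
        likelihood (the published comparisons show the same zero chi-square
        pattern)."""
        model = univariate_model(0.55, 0.0, 0.45, seed=77)
        recs = simulate_cohort(model, 600, 440)
        ace = fit_model(recs, ["trait"], "ACE", FitOptions(seed=0))
        ae = fit_model(recs, ["trait"], "AE", FitOptions(seed=0))
        assert ace.components.c2[0] < 0.1
        cr = compare_models(ace, ae)
        assert cr.delta_chi2 == pytest.approx(0.0, abs=0.2)
        assert cr.aic_delta == pytest.approx(-2.0, abs=0.2)

    def test_trait_order_invariance_of_genetic_correlation(self):
        """Exchanging trait 1 and trait 2 leaves r_a unchanged."""
        from twinchol.core import PhenotypeSchema
        from twinchol.simulate import GeneratingModel, TraitSpec

        thr1 = calibrate_thresholds([0.5, 0.3, 0.2])
        chol = cholesky_from_components((0.45, 0.05, 0.5), thr1,
                                        (0.55, 0.05, 0.4), [0.4],
                                        r_a=0.6, r_c=0.3, r_e=0.1)
        model = GeneratingModel(
            traits=[TraitSpec(PhenotypeSchema("x", "ordinal", 3), thr1),
                    TraitSpec(PhenotypeSchema("y", "binary"), np.array([0.4]))],
            cholesky=chol, seed=123)
        recs = simulate_cohort(model, 250, 180)
        fit_xy = fit_model(recs, ["x", "y"], "AE", FitOptions(seed=0))
        fit_yx = fit_model(recs, ["y", "x"], "AE", FitOptions(seed=0))
        assert fit_xy.components.r_a == pytest.approx(fit_yx.components.r_a, abs=0.02)
        assert fit_xy.minus2_loglik == pytest.approx(fit_yx.minus2_loglik, abs=0.05)

    def test_unknown_model_and_empty_cohort(self):
        with pytest.raises(ValueError):
            fit_model([], ["t"], "ACE")
        model = univariate_model(0.5, 0.1, 0.4, seed=1)
        recs = simulate_cohort(model, 10, 10)
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(recs, ["trait"], "ADE")


class TestProfileCI:
    def test_flat_c2_interval_includes_zero(self):
        """Under AE-generated data the shared-environment share is flat at
        zero: its profile interval must include 0."""
        model = univariate_model(0.6, 0.0, 0.4, seed=9)
        recs = simulate_cohort(model, 600, 440)
        fit = fit_model(recs, ["trait"], "ACE", FitOptions(seed=0))
        ci = profile_ci(fit, "c2")
        assert ci.low == pytest.approx(0.0, abs=1e-6)
        assert ci.low_at_boundary

    def test_rc_boundary_flagged_in_small_cohort(self):
        """A small bivariate cohort cannot pin the shared-environmental
        correlation: the profile hits both domain edges, mirroring intervals
        reported as -1.00 to +1.00."""
        from twinchol.core import PhenotypeSchema
        from twinchol.simulate import GeneratingModel, TraitSpec

        chol = cholesky_from_components((0.45, 0.05, 0.5), [0.0],
                                        (0.5, 0.05, 0.45), [0.8],
                                        r_a=0.5, r_c=0.0, r_e=0.1)
        model = GeneratingModel(
            traits=[TraitSpec(PhenotypeSchema("x", "binary"), np.array([0.0])),
                    TraitSpec(PhenotypeSchema("y", "binary"), np.array([0.8]))],
            cholesky=chol, seed=15)
        recs = simulate_cohort(model, 80, 60)
        fit = fit_model(recs, ["x", "y"], "ACE", FitOptions(seed=0))
        ci = profile_ci(fit, "r_c")
        assert ci.low_at_boundary and ci.low == -1.0
        assert ci.high_at_boundary and ci.high == 1.0

    def test_profile_matches_parametric_bootstrap(self):
        """Profile bounds for heritability agree with a parametric-bootstrap
        percentile interval on a fixed binary AE fixture (scaled-down
        replicate count)."""
        gen_a2 = 0.5
        model = univariate_model(gen_a2, 0.0, 1 - gen_a2, seed=3)
        recs = simulate_cohort(model, 600, 440)
        fit = fit_model(recs, ["trait"], "AE", FitOptions(seed=0))
        ci = profile_ci(fit, "a2")
        a2_hat = fit.components.a2[0]
        boot = []
        for b in range(400):
            bmodel = univariate_model(a2_hat, 0.0, 1 - a2_hat, seed=50_000 + b)
            brecs = simulate_cohort(bmodel, 600, 440)
            bfit = fit_model(brecs, ["trait"], "AE", FitOptions(seed=0))
            boot.append(bfit.components.a2[0])
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assert ci.low == pytest.approx(lo, abs=0.06)
        assert ci.high == pytest.approx(hi, abs=0.06)


class TestPolychoric:
    def test_null_correlation(self, rng):
        x = rng.integers(0, 2, size=50_000)
        y = rng.integers(0, 2, size=50_000)
        rho, _, _ = polychoric_correlation(x, y)
        assert rho == pytest.approx(0.0, abs=0.02)

    def test_perfect_concordance_capped(self):
        x = [0] * 40 + [1] * 60
        rho, _, _ = polychoric_correlation(x, x)
        assert rho == pytest.approx(1.0, abs=1e-5)

    def test_recovers_generating_tetrachoric(self):
        model = univariate_model(1 - 1e-8, 0.0, 1e-8, seed=4)  # DZ corr 0.5
        recs = simulate_cohort(model, 0, 50_000)
        x1 = [r.twin1.phenotypes["trait"] for r in recs]
        x2 = [r.twin2.phenotypes["trait"] for r in recs]
        rho, _, _ = polychoric_correlation(x1, x2)
        assert rho == pytest.approx(0.5, abs=0.02)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            polychoric_correlation([1, 1, 1], [0, 1, 0])
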