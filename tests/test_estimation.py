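"""Mixed-effects estimation: individual fits, OFV, population fit, search."""

import numpy as np
import pytest

from ugtphen import DoseEvent, StructuralParams, simulate_profile
from ugtphen.population import (PopulationModel, apply_residual_error,
                                eta_shrinkage, sample_individuals)
from ugtphen.estimation import (CovariateEffect, backward_retained,
                                fit_individual, fit_population,
                                format_fit_report, forward_admissible, ofv)


TIMES8 = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 24.0])


def small_pop(theta, cv=30.0):
    return PopulationModel(theta, omega_cv={"cl_f": cv, "v_f": cv},
                           corr_cl_v=0.3, sigma_ral=0.15, sigma_glu=0.18)


class TestFitIndividual:
    def test_noise_free_recovery(self, theta, single_dose):
        times = np.array([0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 10, 12,
                          16, 20, 24, 30])
        parent, metab = simulate_profile(theta, single_dose, times)
        init = StructuralParams(cl_f=20, v_f=80, ka=2, mtt=2, nn=0.5,
                                fmet=0.06, cl_glu=1.2)
        est, diag = fit_individual(parent, metab, init)
        assert diag["converged"]
        for name in ("cl_f", "v_f", "ka", "mtt", "nn", "fmet", "cl_glu"):
            assert getattr(est, name) == pytest.approx(
                getattr(theta, name), rel=5e-3), name

    def test_zero_dose_rejected(self, theta):
        times = np.array([0.5, 1.0, 2.0])
        parent, metab = simulate_profile(theta, [DoseEvent(0.0, 0.0)], times)
        with pytest.raises(ValueError, match="no non-zero dose|no information"):
            fit_individual(parent, metab, theta)

    def test_underdetermined_rejected(self, theta, single_dose):
        parent, metab = simulate_profile(theta, single_dose,
                                         np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="under-determined"):
            fit_individual(parent, metab, theta)

    def test_fixed_mask_respected(self, theta, single_dose):
        times = np.linspace(0.5, 24, 12)
        parent, metab = simulate_profile(theta, single_dose, times)
        init = theta.replace(cl_f=30.0)
        est, _ = fit_individual(parent, metab, init,
                                fixed=("f", "v_glu", "ka", "nn", "mtt"))
        assert est.ka == theta.ka and est.nn == theta.nn
        assert est.cl_f == pytest.approx(theta.cl_f, rel=1e-3)


class TestOfv:
    def test_degenerate_no_iiv_equals_gaussian_loglik(self, theta,
                                                      single_dose):
        # with omega empty the OFV is the plain fixed-effect expression
        parent, metab = simulate_profile(theta, single_dose, TIMES8)
        rng = np.random.default_rng(0)
        parent = apply_residual_error(parent, 0.2, rng)
        metab = apply_residual_error(metab, 0.25, rng)
        pop = PopulationModel(theta, omega_cv={}, sigma_ral=0.2,
                              sigma_glu=0.25)
        got = ofv(pop, [(parent, metab)])
        pred_p, pred_m = simulate_profile(theta, single_dose, TIMES8)
        rp = np.log(parent.concentrations) - np.log(pred_p.concentrations)
        rm = np.log(metab.concentrations) - np.log(pred_m.concentrations)
        expected = (np.sum(np.log(2 * np.pi * 0.2**2) + rp**2 / 0.2**2)
                    + np.sum(np.log(2 * np.pi * 0.25**2) + rm**2 / 0.25**2))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_smaller_sigma_than_generating_increases_ofv(self, theta,
                                                         single_dose):
        # dense schedule so the realized residual SD concentrates around
        # the generating sigma and the likelihood ordering is decisive
        times = np.linspace(0.25, 24.0, 100)
        parent, metab = simulate_profile(theta, single_dose, times)
        rng = np.random.default_rng(1)
        parent = apply_residual_error(parent, 0.3, rng)
        metab = apply_residual_error(metab, 0.3, rng)
        matched = PopulationModel(theta, omega_cv={}, sigma_ral=0.3,
                                  sigma_glu=0.3)
        halved = PopulationModel(theta, omega_cv={}, sigma_ral=0.15,
                                 sigma_glu=0.15)
        assert ofv(halved, [(parent, metab)]) > ofv(matched, [(parent, metab)])

    def test_duplicate_observation_adds_its_exact_contribution(self, theta,
                                                               single_dose):
        # at sigma >= 1 every row's contribution log(2 pi sigma^2)+r^2/s^2
        # is positive, so the OFV strictly increases; the smaller published
        # sigmas can make a well-fitted row's contribution negative, which
        # is why the assertion is on the exact value, not just the sign
        parent, metab = simulate_profile(theta, single_dose, TIMES8)
        rng = np.random.default_rng(2)
        parent = apply_residual_error(parent, 0.5, rng)
        pop = PopulationModel(theta, omega_cv={}, sigma_ral=1.0,
                              sigma_glu=1.0)
        base = ofv(pop, [(parent, metab)])
        # duplicate the 4 h parent sample by a twin profile carrying it
        t_new = np.append(parent.times, 24.5)
        c_new = np.append(parent.concentrations,
                          parent.concentrations[-1])
        parent2 = parent.__class__(parent.subject_id, parent.analyte, t_new,
                                   c_new, parent.doses)
        with_dup = ofv(pop, [(parent2, metab)])
        pred, _ = simulate_profile(theta, single_dose, np.array([24.5]))
        r = np.log(c_new[-1]) - np.log(pred.concentrations[0])
        contribution = np.log(2 * np.pi * 1.0) + r**2
        assert with_dup - base == pytest.approx(contribution, rel=1e-6)
        assert with_dup > base

    def test_invariant_to_subject_order(self, pop_model, simulate_cohort_data):
        _, data = simulate_cohort_data(pop_model, 8, TIMES8, seed=3)
        assert ofv(pop_model, data) == pytest.approx(
            ofv(pop_model, data[::-1]), rel=1e-9)

    def test_laplace_close_to_foce_on_rich_data(self, pop_model, simulate_cohort_data):
        _, data = simulate_cohort_data(pop_model, 6, TIMES8, seed=4)
        a = ofv(pop_model, data, method="foce_i")
        b = ofv(pop_model, data, method="laplace")
        assert b == pytest.approx(a, rel=0.02)

    def test_truth_beats_perturbed_model(self, pop_model, simulate_cohort_data):
        # likelihood ordering: the generating model never scores worse than
        # one with a structural parameter perturbed 3-fold
        _, data = simulate_cohort_data(pop_model, 10, TIMES8, seed=5)
        perturbed = PopulationModel(
            pop_model.theta.replace(cl_f=pop_model.theta.cl_f * 3.0),
            omega_cv=dict(pop_model.omega_cv),
            corr_cl_v=pop_model.corr_cl_v,
            sigma_ral=pop_model.sigma_ral, sigma_glu=pop_model.sigma_glu)
        assert ofv(pop_model, data) < ofv(perturbed, data)


class TestFitPopulation:
    @pytest.fixture(scope="class")
    def small_fit(self, theta):
        pop = small_pop(theta)
        rng = np.random.default_rng(11)
        inds = sample_individuals(pop, 12, rng)
        data = []
        for ind in inds:
            p, m = simulate_profile(ind.params, [DoseEvent(0.0, 400.0)],
                                    TIMES8, subject_id=ind.subject_id)
            data.append((apply_residual_error(p, 0.15, rng),
                         apply_residual_error(m, 0.18, rng)))
        init = PopulationModel(
            theta.replace(cl_f=30.0, v_f=100.0),
            omega_cv={"cl_f": 40.0, "v_f": 40.0}, corr_cl_v=0.1,
            sigma_ral=0.2, sigma_glu=0.2)
        fit = fit_population(data, init, n_starts=1, seed=0, maxiter=80,
                             compute_rse=True)
        return pop, data, init, fit

    def test_converges_and_recovers_reasonably(self, small_fit):
        pop, data, init, fit = small_fit
        assert fit.convergence == "converged"
        # n=12 subjects: generous bands, this is a smoke-level recovery
        assert fit.theta_hat.cl_f == pytest.approx(pop.theta.cl_f, rel=0.25)
        assert fit.theta_hat.v_f == pytest.approx(pop.theta.v_f, rel=0.25)

    def test_shrinkage_consistent_with_own_ebes(self, small_fit):
        _, _, _, fit = small_fit
        from ugtphen.population import cv_to_omega
        for name, ebes in fit.ebes.items():
            omega_sd = float(cv_to_omega(fit.omega_cv_hat[name]))
            assert fit.shrinkage[name] == pytest.approx(
                eta_shrinkage(ebes, omega_sd), abs=1e-9)

    def test_rse_reported_for_free_parameters(self, small_fit):
        _, _, _, fit = small_fit
        for key in ("theta:cl_f", "theta:v_f", "omega:cl_f", "sigma_ral"):
            assert key in fit.rse
        finite = [v for v in fit.rse.values() if np.isfinite(v)]
        assert len(finite) >= 5
        assert all(v >= 0 for v in finite)

    def test_report_formatting(self, small_fit):
        _, _, _, fit = small_fit
        text = format_fit_report(fit)
        assert "CL_RAL/F" in text and "FIXED" in text and "OFV" in text

    def test_nested_model_never_fits_worse(self, small_fit):
        # freeing a fixed structural parameter cannot increase the OFV
        pop, data, init, fit = small_fit
        refit_restricted = fit_population(
            data, fit.to_population_model(),
            fixed=("f", "v_glu", "ka", "mtt", "nn"),
            n_starts=1, seed=0, maxiter=40, compute_rse=False)
        refit_free = fit_population(
            data, refit_restricted.to_population_model(),
            n_starts=1, seed=0, maxiter=40, compute_rse=False)
        assert refit_free.ofv <= refit_restricted.ofv + 1e-6

    def test_theta_recovery_with_omega_fixed_on_clean_data(self, theta):
        # no-eta, no-noise data, omega/sigma fixed: theta within 1%
        data = []
        for i in range(8):
            p, m = simulate_profile(theta, [DoseEvent(0.0, 400.0)],
                                    TIMES8, subject_id=f"S{i}")
            data.append((p, m))
        init = PopulationModel(
            theta.replace(cl_f=30.0, v_f=120.0, fmet=0.05),
            omega_cv={"cl_f": 10.0, "v_f": 10.0}, corr_cl_v=0.0,
            sigma_ral=0.1, sigma_glu=0.1)
        fit = fit_population(
            data, init,
            fixed=("f", "v_glu", "omega:cl_f", "omega:v_f", "corr_cl_v",
                   "sigma_ral", "sigma_glu"),
            n_starts=1, seed=0, maxiter=150, compute_rse=False)
        for name in ("cl_f", "v_f", "ka", "mtt", "nn", "fmet", "cl_glu"):
            assert getattr(fit.theta_hat, name) == pytest.approx(
                getattr(theta, name), rel=0.01), name

    def test_too_few_subjects_rejected(self, theta, single_dose):
        p, m = simulate_profile(theta, single_dose, TIMES8)
        with pytest.raises(ValueError, match="subjects"):
            fit_population([(p, m)], small_pop(theta))


class TestCovariateDecisionRules:
    def test_forward_threshold_boundary(self):
        assert not forward_admissible(3.83, 30.0, 25.0)
        assert forward_admissible(3.84, 30.0, 25.0)

    def test_forward_requires_iiv_decline(self):
        assert not forward_admissible(20.0, 30.0, 30.0)
        assert not forward_admissible(20.0, 30.0, 31.0)
        assert forward_admissible(20.0, 30.0, 29.9)

    def test_backward_threshold_boundary(self):
        assert not backward_retained(10.79)
        assert backward_retained(10.8)

    def test_covariate_effect_forms(self):
        eff = CovariateEffect("cl_f", "bodyweight", "power", ref=55.0)
        np.testing.assert_allclose(
            eff.multiplier(np.array([55.0, 110.0]), 0.75),
            [1.0, 2.0**0.75])
        lin = CovariateEffect("cl_f", "age", "linear", ref=50.0)
        np.testing.assert_allclose(
            lin.multiplier(np.array([50.0, 60.0]), 0.5), [1.0, 1.1])
        cat = CovariateEffect("cl_f", "sex", "fractional", ref=0.0)
        np.testing.assert_allclose(
            cat.multiplier(np.array([0.0, 1.0]), -0.3), [1.0, 0.7])
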