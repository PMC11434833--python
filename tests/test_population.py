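"""Covariate model, random effects, residual error, and the joint density."""

import math

import numpy as np
import pytest
from dataclasses import replace

import peritopk as pk
from peritopk.population import OCCASION_SWITCH_H


class TestIndividualParams:
    def test_piperacillin_typical_patient(self, pip_params):
        cov = pk.CovariateVector(age=66, weight=83, renal_category="A")
        p = pk.individual_params(pip_params, cov)
        assert p.V1 == pytest.approx(30.25, abs=0.01)
        assert p.Cl1 == pytest.approx(38.739)
        assert p.V2 == 5.0 and p.Q == pytest.approx(23.833)

    def test_piperacillin_crrt_clearance(self, pip_params):
        cov = pk.CovariateVector(age=66, weight=83, renal_category="B")
        p = pk.individual_params(pip_params, cov)
        assert p.Cl1 == pytest.approx(5.16, abs=0.01)

    def test_tazobactam_renal_impairment_clearance(self, taz_params):
        cov = pk.CovariateVector(age=66, weight=83, renal_category="C")
        p = pk.individual_params(taz_params, cov)
        assert p.Cl1 == pytest.approx(0.70, abs=0.01)

    def test_zero_betas_and_effects_reproduce_population_values(self):
        pop = pk.PopulationParams(
            drug="x", V1pop=20, V2pop=5, Qpop=20, Cl1pop=10, Cl2pop=3
        )
        cov = pk.CovariateVector(age=50, weight=70, renal_category="A")
        p = pk.individual_params(pop, cov)
        assert (p.V1, p.V2, p.Q, p.Cl1, p.Cl2) == (20, 5, 20, 10, 3)

    def test_category_d_maps_to_reference(self, pip_params):
        eta = pk.RandomEffects(eta_v1=0.3, eta_cl1=-0.2, eta_cl2=0.1)
        a = pk.individual_params(
            pip_params, pk.CovariateVector(60, 80, "A"), eta
        )
        d = pk.individual_params(
            pip_params, pk.CovariateVector(60, 80, "D"), eta
        )
        assert a == d

    def test_parameters_positive_for_any_finite_eta(self, pip_params):
        eta = pk.RandomEffects(eta_v1=-8, eta_cl1=9, eta_cl2=-7,
                               eta_occ_cl1=(6, -6))
        cov = pk.CovariateVector(age=90, weight=150, renal_category="B")
        for occ in (1, 2):
            p = pk.individual_params(pip_params, cov, eta, occasion=occ)
            assert min(p.V1, p.V2, p.Q, p.Cl1, p.Cl2) > 0

    def test_monotone_in_category_beta(self, pip_params):
        cov = pk.CovariateVector(age=66, weight=83, renal_category="B")
        cl1 = [
            pk.individual_params(replace(pip_params, betaCl1_catB=b), cov).Cl1
            for b in (-2.016, -1.0, -0.5, 0.0)
        ]
        assert cl1 == sorted(cl1)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            pk.CovariateVector(age=66, weight=83, renal_category="E")


class TestRandomEffects:
    def test_zero_variability_gives_zero_effects(self, pip_noiseless):
        effects = pk.sample_random_effects(pip_noiseless, 10, rng=np.random.default_rng(0))
        for e in effects:
            assert e.eta_v1 == e.eta_cl1 == e.eta_cl2 == 0.0
            assert e.eta_occ_cl1 == (0.0, 0.0)

    def test_sample_sd_matches_omega(self, pip_params):
        effects = pk.sample_random_effects(
            pip_params, 100_000, rng=np.random.default_rng(7)
        )
        sd = np.std([e.eta_cl1 for e in effects])
        assert sd == pytest.approx(0.661, rel=0.01)
        sd_occ = np.std([k for e in effects for k in e.eta_occ_cl1])
        assert sd_occ == pytest.approx(0.391, rel=0.01)

    def test_seeded_draws_are_reproducible(self, pip_params):
        a = pk.sample_random_effects(pip_params, 50, rng=np.random.default_rng(42))
        b = pk.sample_random_effects(pip_params, 50, rng=np.random.default_rng(42))
        assert a == b


class TestResidualError:
    def test_zero_coefficient_is_exact(self, pip_noiseless):
        assert pk.apply_residual_error(
            50.0, "plasma", pip_noiseless, np.random.default_rng(0)
        ) == 50.0

    def test_zero_concentration_stays_zero(self, pip_params):
        assert pk.apply_residual_error(
            0.0, "peritoneal", pip_params, np.random.default_rng(0)
        ) == 0.0

    def test_noise_sd_is_proportional(self, pip_params):
        rng = np.random.default_rng(3)
        y = pk.apply_residual_error(
            np.full(100_000, 100.0), "plasma", pip_params, rng
        )
        assert np.std(y) == pytest.approx(20.7, rel=0.01)

    def test_unknown_compartment_rejected(self, pip_params):
        with pytest.raises(ValueError):
            pk.apply_residual_error(1.0, "urine", pip_params)

    def test_negative_draws_floored(self):
        pop = pk.PopulationParams(drug="x", V1pop=20, V2pop=5, Qpop=20,
                                  Cl1pop=10, Cl2pop=3, bC1=5.0)
        with pytest.warns(UserWarning):
            y = pk.apply_residual_error(
                np.full(200, 1.0), "plasma", pop, np.random.default_rng(0)
            )
        assert np.min(y) == 0.0


class TestLogLikelihood:
    def setup_method(self):
        self.sched = pk.DoseSchedule.loading_plus_continuous(4000, 0.5, 16000, 60)
        self.cov = pk.CovariateVector(age=66, weight=83, renal_category="A")

    def test_exact_prediction_closed_form(self, pip_params):
        eta = pk.RandomEffects()
        c = pk.predict_concentrations(
            pip_params, self.cov, eta, self.sched, [50.0], ["plasma"]
        )[0]
        ll = pk.log_likelihood(
            pip_params, self.cov, eta, self.sched, [50.0], ["plasma"], [c]
        )
        b = pip_params.bC1
        expected = -math.log(b * c * math.sqrt(2 * math.pi))
        # eta priors at zero contribute their normalisation constants
        for w in (pip_params.omegaV1, pip_params.omegaCl1, pip_params.omegaCl2,
                  pip_params.gammaCl1, pip_params.gammaCl1):
            expected += -math.log(w * math.sqrt(2 * math.pi))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_eta_shifts_joint_density_by_its_prior(self, pip_params):
        # with predictions held fixed, adding an occasion-2 eta changes the
        # joint exactly by the normal log-prior difference
        eta0 = pk.RandomEffects()
        eta1 = pk.RandomEffects(eta_occ_cl1=(0.0, 0.7))
        args = (self.sched, [0.5], ["plasma"])
        y = pk.predict_concentrations(pip_params, self.cov, eta0, *args)
        # occasion-2 eta does not affect an occasion-1 observation
        ll0 = pk.log_likelihood(pip_params, self.cov, eta0, *args, y)
        ll1 = pk.log_likelihood(pip_params, self.cov, eta1, *args, y)
        g = pip_params.gammaCl1
        assert ll1 - ll0 == pytest.approx(-0.5 * (0.7 / g) ** 2, abs=1e-10)

    def test_matches_brute_force_density_product(self, pip_params):
        from scipy.stats import norm

        eta = pk.RandomEffects(eta_v1=0.1, eta_cl1=-0.2, eta_cl2=0.05,
                               eta_occ_cl1=(0.03, -0.04))
        times = [0.5, 50.0, 50.0]
        comps = ["plasma", "plasma", "peritoneal"]
        values = [95.0, 14.0, 11.0]
        preds = pk.predict_concentrations(
            pip_params, self.cov, eta, self.sched, times, comps
        )
        brute = 0.0
        for y, c, comp in zip(values, preds, comps):
            b = pip_params.bC1 if comp == "plasma" else pip_params.bC2
            brute += norm.logpdf(y, loc=c, scale=b * c)
        for e, w in ((eta.eta_v1, pip_params.omegaV1),
                     (eta.eta_cl1, pip_params.omegaCl1),
                     (eta.eta_cl2, pip_params.omegaCl2),
                     (eta.eta_occ_cl1[0], pip_params.gammaCl1),
                     (eta.eta_occ_cl1[1], pip_params.gammaCl1)):
            brute += norm.logpdf(e, scale=w)
        ll = pk.log_likelihood(
            pip_params, self.cov, eta, self.sched, times, comps, values
        )
        assert ll == pytest.approx(brute, abs=1e-10)


class TestOccasionSwitching:
    def test_profile_continuous_across_switch(self, pip_params):
        eta = pk.RandomEffects(eta_occ_cl1=(0.5, -0.5))
        cov = pk.CovariateVector(age=66, weight=83, renal_category="A")
        sched = pk.DoseSchedule.loading_plus_continuous(4000, 0.5, 16000, 60)
        t = [OCCASION_SWITCH_H - 1e-6, OCCASION_SWITCH_H + 1e-6]
        c = pk.predict_concentrations(pip_params, cov, eta, sched, t,
                                      ["plasma", "plasma"])
        assert c[0] == pytest.approx(c[1], rel=1e-4)


class TestParameterFiles:
    def test_round_trip(self, tmp_path, pip_params, taz_params):
        for pop in (pip_params, taz_params):
            path = tmp_path / f"{pop.drug}.yaml"
            pk.save_population_params(pop, path)
            back = pk.load_population_params(path)
            assert back == pop
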