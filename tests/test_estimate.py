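"""FOCE estimation: objective correctness, EBEs, shrinkage, covariate search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import bepopk as bp
from bepopk import estimate as est
from bepopk.population import PARAM_ORDER, CovariateEffect
from oracles import gauss_hermite_ofv, small_instance


class TestObjective:
    def test_matches_quadrature_oracle_on_small_instances(self):
        rng = np.random.default_rng(7)
        for i in range(6):
            live = ("cl",) if i % 2 == 0 else ("cl", "ka")
            pop, tbl = small_instance(rng, n_sub=1 + i % 2, live=live)
            foce = bp.foce_objective(pop, tbl)
            quad = gauss_hermite_ofv(pop, tbl, live)
            assert abs(foce - quad) < 1.0

    def test_zero_omega_limit_is_fixed_effects_deviance(self, pop):
        tbl = bp.apply_lloq_filter(
            bp.simulate_study(bp.adult_design(4), pop, np.random.default_rng(8))
        )
        small = dataclasses.replace(
            pop, iiv_cv={k: 1e-5 for k in PARAM_ORDER}, corr_cl_v=0.0, corr_cl_alag=0.0
        )
        # direct eta = 0 weighted least-squares -2LL
        data = est.compile_data(tbl)
        theta = np.array([small.theta[k] for k in PARAM_ORDER])
        typ = est._typical_matrix(theta, data, [])
        f = est._pred_eta(data, typ, np.zeros((data.n_sub, 4)))
        v = small.sigma_prop**2 * f**2 + small.sigma_add**2
        direct = np.sum(np.log(2 * np.pi * v) + (data.obs_y - f) ** 2 / v)
        assert bp.foce_objective(small, tbl) == pytest.approx(direct, abs=0.05)

    def test_duplicating_subjects_doubles_ofv(self, pop):
        tbl = bp.apply_lloq_filter(
            bp.simulate_study(bp.adult_design(3), pop, np.random.default_rng(9))
        )
        dup = tbl.copy()
        dup["ID"] = dup["ID"] + 100
        both = pd.concat([tbl, dup], ignore_index=True)
        assert bp.foce_objective(pop, both) == pytest.approx(
            2 * bp.foce_objective(pop, tbl), rel=1e-9
        )


class TestFit:
    def test_noise_free_thetas_recovered_to_four_digits(self, no_variability_pop):
        # zero IIV, microscopic residual noise: thetas are exactly identified
        truth = dataclasses.replace(no_variability_pop, sigma_prop=1e-5)
        tbl = bp.apply_lloq_filter(
            bp.simulate_two_study_dataset(truth, np.random.default_rng(10), 8, 8)
        )
        perturbed = dataclasses.replace(
            truth, theta={k: v * 1.2 for k, v in truth.theta.items()}
        )
        spec = est.ModelSpec(
            inits=perturbed, estimate_sigma_prop=False, estimate_omega=False
        )
        fit = bp.fit_foce(tbl, spec)
        for k in PARAM_ORDER:
            assert fit.params.theta[k] == pytest.approx(truth.theta[k], rel=1e-4)

    def test_optimum_not_worse_than_inits(self, two_study_dataset, pop):
        spec = est.ModelSpec(inits=pop, max_iter=15)
        fit = bp.fit_foce(two_study_dataset, spec)
        assert fit.ofv <= bp.foce_objective(pop, two_study_dataset) + 1e-6

    def test_standard_errors_reported_on_natural_scale(self, pop):
        tbl = bp.apply_lloq_filter(
            bp.simulate_two_study_dataset(pop, np.random.default_rng(11), 12, 10)
        )
        fit = bp.fit_foce(tbl, est.ModelSpec(inits=pop, max_iter=25), compute_se=True)
        assert fit.rse is not None
        assert np.isfinite(fit.rse["theta_cl"])
        assert 0 < fit.rse["theta_cl"] < 60


class TestEmpiricalBayes:
    def test_subject_without_observations_gets_prior_mode(self, pop):
        tbl = bp.simulate_study(bp.adult_design(2), pop, np.random.default_rng(12))
        dose_only = tbl[(tbl["ID"] == 2) & (tbl["EVID"] == 1)]
        mixed = pd.concat(
            [bp.apply_lloq_filter(tbl[tbl["ID"] == 1]), dose_only], ignore_index=True
        )
        ebe = est.empirical_bayes(pop, mixed)
        assert np.allclose(ebe.loc[2].to_numpy(), 0.0)
        assert not np.allclose(ebe.loc[1].to_numpy(), 0.0)

    def test_dense_low_noise_subject_recovers_true_parameters(self, pop):
        quiet = dataclasses.replace(pop, sigma_prop=0.01, additive_error=0.001)
        rng = np.random.default_rng(13)
        cov = bp.Covariates(wt=70.0, age=25.0, scr=0.9, egfr=110.0, sex="male")
        ind = bp.population.sample_individual(quiet, cov, rng)
        times = np.linspace(0.4, 14.0, 40)
        pred = bp.pk_core.conc_single_dose(ind.params, 10.0, times)
        obs = bp.population.residual_error(pred, quiet, rng=rng)
        rows = [
            {"ID": 1, "TIME": 0.0, "EVID": 1, "AMT": 10.0, "DV": np.nan, "BLQ": 0,
             "WT": 70.0, "AGE": 25.0, "SCR": 0.9, "EGFR": 110.0, "SEX": 0}
        ]
        rows += [
            {"ID": 1, "TIME": t, "EVID": 0, "AMT": np.nan, "DV": y, "BLQ": 0,
             "WT": 70.0, "AGE": 25.0, "SCR": 0.9, "EGFR": 110.0, "SEX": 0}
            for t, y in zip(times, obs)
        ]
        ebe = est.empirical_bayes(quiet, pd.DataFrame(rows))
        typ = bp.allometric_scale(quiet, cov)
        realized_cl = typ.cl * np.exp(ebe.loc[1, "eta_cl"])
        realized_v = typ.v * np.exp(ebe.loc[1, "eta_v"])
        assert realized_cl == pytest.approx(ind.params.cl, rel=0.02)
        assert realized_v == pytest.approx(ind.params.v, rel=0.02)

    def test_invariant_to_subject_ordering(self, pop):
        tbl = bp.apply_lloq_filter(
            bp.simulate_study(bp.adult_design(5), pop, np.random.default_rng(14))
        )
        shuffled = tbl.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = est.empirical_bayes(pop, tbl)
        b = est.empirical_bayes(pop, shuffled)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestShrinkage:
    def test_well_dispersed_ebes_have_low_shrinkage(self, pop):
        om = pop.omega()
        etas = np.random.default_rng(15).multivariate_normal(np.zeros(4), om, 5000)
        shr = est.compute_shrinkage(etas, om)
        for k in PARAM_ORDER:
            assert abs(shr[k]) < 5.0

    def test_all_zero_ebes_shrink_fully(self, pop):
        shr = est.compute_shrinkage(np.zeros((50, 4)), pop.omega())
        for k in PARAM_ORDER:
            assert shr[k] == pytest.approx(100.0)

    def test_zero_omega_reported_absent(self, pop):
        om = pop.omega().copy()
        om[0, :] = om[:, 0] = 0.0
        shr = est.compute_shrinkage(np.zeros((10, 4)), om)
        assert np.isnan(shr["ka"])

    def test_sparse_pediatric_design_shrinks_ka_more_than_cl(self, pop):
        tbl = bp.apply_lloq_filter(
            bp.simulate_study(bp.pediatric_design(30), pop, np.random.default_rng(16))
        )
        ebe = est.empirical_bayes(pop, tbl)
        shr = est.compute_shrinkage(ebe.to_numpy(), pop.omega())
        assert shr["ka"] > shr["cl"]


class TestStepwise:
    def test_thresholds_are_strict_and_ties_break_by_order(self, monkeypatch, pop):
        # drive the selection logic with canned OFVs: a candidate at exactly
        # the forward threshold is not selected; the largest drop wins
        cands = [
            CovariateEffect("cl", "age", "exponential", 0.0, 5.0),
            CovariateEffect("cl", "scr", "exponential", 0.0, 0.4),
            CovariateEffect("v", "age", "exponential", 0.0, 5.0),
        ]
        ofvs = {
            (): 1000.0,
            ("age->cl",): 1000.0 - 3.84,   # exactly at the threshold: rejected
            ("scr->cl",): 1000.0 - 10.0,   # clear winner
            ("age->v",): 1000.0 - 5.0,
            ("scr->cl", "age->cl"): 990.0 - 2.0,
            ("scr->cl", "age->v"): 990.0 - 3.0,
        }

        def fake_fit(tbl, spec=None, compute_se=False):
            key = tuple(f"{e.covariate}->{e.parameter}" for e in spec.covariate_effects)
            ofv = ofvs[key]
            return est.FitResult(
                params=dataclasses.replace(
                    pop, covariate_effects=list(spec.covariate_effects)
                ),
                ofv=ofv, converged=True, n_subjects=10, n_obs=50,
                ebe=pd.DataFrame(), shrinkage={},
            )

        monkeypatch.setattr(est, "fit_foce", fake_fit)
        res = est.stepwise_covariates(pd.DataFrame(), est.ModelSpec(inits=pop), cands)
        # forward: scr->cl enters (dOFV 10), then neither addition clears 3.84;
        # backward: removing scr->cl would worsen by 10 > 6.63, so it stays
        assert [(e.covariate, e.parameter) for e in res.selected] == [("scr", "cl")]
        assert res.trace[0]["step"] == "forward"

    def test_backward_elimination_drops_marginal_covariate(self, monkeypatch, pop):
        cands = [CovariateEffect("cl", "scr", "exponential", 0.0, 0.4)]
        ofvs = {(): 1000.0, ("scr->cl",): 1000.0 - 5.0}

        def fake_fit(tbl, spec=None, compute_se=False):
            key = tuple(f"{e.covariate}->{e.parameter}" for e in spec.covariate_effects)
            return est.FitResult(
                params=dataclasses.replace(
                    pop, covariate_effects=list(spec.covariate_effects)
                ),
                ofv=ofvs[key], converged=True, n_subjects=10, n_obs=50,
                ebe=pd.DataFrame(), shrinkage={},
            )

        monkeypatch.setattr(est, "fit_foce", fake_fit)
        res = est.stepwise_covariates(pd.DataFrame(), est.ModelSpec(inits=pop), cands)
        # enters forward (5 > 3.84) but does not survive backward (5 <= 6.63)
        assert res.selected == []

    def test_strong_simulated_covariate_is_selected(self, pop):
        # SCR effect on CL large enough that the LRT must find it
        effect = CovariateEffect("cl", "scr", "exponential", 2.0, 0.87)
        truth = dataclasses.replace(pop, covariate_effects=[effect])
        tbl = bp.apply_lloq_filter(
            bp.simulate_study(bp.adult_design(16), truth, np.random.default_rng(17))
        )
        cand = [CovariateEffect("cl", "scr", "exponential", 0.0, 0.87)]
        res = est.stepwise_covariates(
            tbl, est.ModelSpec(inits=pop, max_iter=40), cand
        )
        assert [(e.covariate, e.parameter) for e in res.selected] == [("scr", "cl")]
        assert res.final_fit.params.covariate_effects[-1].coefficient > 0

    def test_null_data_mostly_selects_nothing(self, pop):
        # type-I control at the 3.84 threshold, scaled down to two replicates
        # and a two-candidate set to keep the fits affordable
        cands = [
            CovariateEffect("cl", "scr", "exponential", 0.0, 0.87),
            CovariateEffect("cl", "egfr", "exponential", 0.0, 110.0),
        ]
        tbl = bp.apply_lloq_filter(
            bp.simulate_study(bp.adult_design(16), pop, np.random.default_rng(18))
        )
        res = est.stepwise_covariates(
            tbl, est.ModelSpec(inits=pop, max_iter=40), cands
        )
        assert res.selected == []
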