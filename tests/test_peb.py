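"""Group-level PEB, Bayesian model reduction, and model comparison."""

import numpy as np
import pytest
from scipy import stats

import fsdcm
from fsdcm import PEBConfig, PriorSpec
from fsdcm.peb import gaussian_model_reduction
from conftest import make_posteriors


class TestGaussianModelReduction:
    def test_matches_conjugate_evidence_oracle(self):
        """BMR must reproduce exact linear-Gaussian evidence ratios."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            D = rng.standard_normal((3, 2))
            R = np.diag(rng.uniform(0.5, 2.0, 3))          # obs noise cov
            mu0 = rng.standard_normal(2)
            S0 = np.diag(rng.uniform(0.5, 2.0, 2))
            mu_new = rng.standard_normal(2)
            S_new = np.diag(rng.uniform(0.2, 3.0, 2))
            y = rng.standard_normal(3)

            def posterior_and_logz(mu, S):
                P = np.linalg.inv(S) + D.T @ np.linalg.inv(R) @ D
                m = np.linalg.solve(
                    P, np.linalg.solve(S, mu) + D.T @ np.linalg.solve(R, y))
                logz = stats.multivariate_normal.logpdf(
                    y, D @ mu, R + D @ S @ D.T)
                return m, np.linalg.inv(P), logz

            m, S, logz = posterior_and_logz(mu0, S0)
            m_ref, S_ref, logz_new = posterior_and_logz(mu_new, S_new)
            m_red, S_red, dF = gaussian_model_reduction(
                mu0, S0, m, S, mu_new, S_new)
            assert dF == pytest.approx(logz_new - logz, abs=1e-8)
            assert m_red == pytest.approx(m_ref, abs=1e-8)
            assert S_red == pytest.approx(S_ref, abs=1e-8)


class TestFitPEB:
    def test_consensus_cohort_returns_shared_mean(self, records):
        # degenerate consensus: identical, very precise subject posteriors.
        # (High precision matters: the hierarchy removes the first-level
        # prior from each subject, which de-shrinks imprecise means.)
        shared = np.array([0.3, -0.2, 0.1, 0.05])
        posts = make_posteriors(np.tile(shared, (19, 1)),
                                cov=np.eye(4) * 1e-8)
        design = fsdcm.build_design_matrix(records, "null")
        model = fsdcm.fit_peb(posts, design,
                              config=PEBConfig(beta_prior_scale=1e6))
        assert model.beta_mean[0] == pytest.approx(shared, abs=1e-6)

    def test_null_design_equals_precision_weighted_closed_form(self, records):
        rng = np.random.default_rng(3)
        means = rng.standard_normal((19, 4)) * 0.2
        posts = make_posteriors(means, cov=np.eye(4) * 0.01)
        design = fsdcm.build_design_matrix(records, "null")
        lg = np.log(100.0)
        priors = PriorSpec()
        model = fsdcm.fit_peb(posts, design, priors,
                              PEBConfig(fixed_log_gamma=float(lg)))
        # independent closed form: evidence-weighted Bayesian mean with
        # weights ((P_i - Lambda0)^-1 + Gamma)^-1
        L0 = np.linalg.inv(priors.theta_cov)
        Gamma = np.eye(4) / np.exp(lg)
        Cb_inv = np.linalg.inv(priors.theta_cov)  # null design: ms = 1
        num = np.zeros(4)
        den = Cb_inv.copy()
        for p in posts:
            P = np.linalg.inv(p.covariance)
            Pd = P - L0
            m_d = np.linalg.solve(Pd, P @ p.mean)
            W = np.linalg.inv(np.linalg.inv(Pd) + Gamma)
            num += W @ m_d
            den += W
        beta_closed = np.linalg.solve(den, num)
        assert model.beta_mean[0] == pytest.approx(beta_closed, abs=1e-8)

    def test_recovers_a_known_covariate_effect(self):
        records = fsdcm.generate_clinical(19, seed=5)
        design = fsdcm.build_design_matrix(records, "total positive")
        rng = np.random.default_rng(6)
        beta_true = np.zeros((4, 4))
        beta_true[1, 0] = 0.5          # within-DLPFC inhibition only
        thetas = design.values @ beta_true + 0.05 * rng.standard_normal((19, 4))
        # emulate first-level posteriors: shrink the true parameters by the
        # first-level prior exactly as a precision-16 prior would
        post_prec, prior_prec = 100.0, 16.0
        means = thetas * (post_prec - prior_prec) / post_prec
        posts = make_posteriors(means, cov=np.eye(4) / post_prec)
        model = fsdcm.fit_peb(posts, design)
        idx = 4 * 1 + 0
        sd = np.sqrt(model.beta_covariance[idx, idx])
        assert abs(model.beta_mean[1, 0] - 0.5) < 2 * sd
        effects = fsdcm.effect_probabilities(model)
        assert effects[0].posterior_prob > 0.95
        assert all(e.posterior_prob < 0.95 for e in effects[1:])

    def test_imprecise_subjects_barely_move_the_group_mean(self, records):
        rng = np.random.default_rng(8)
        means = rng.standard_normal((19, 4)) * 0.2
        posts = make_posteriors(means, cov=np.eye(4) * 0.01)
        design = fsdcm.build_design_matrix(records, "null")
        cfg = PEBConfig(fixed_log_gamma=float(np.log(100.0)))
        base = fsdcm.fit_peb(posts, design, config=cfg).beta_mean[0]

        outlier = np.array([1.0, 1.0, -1.0, -1.0])

        def refit_with_extra(cov_scale):
            extra = fsdcm.SubjectPosterior(
                "20", outlier, np.eye(4) * 0.01 * cov_scale, 0.0, 50.0)
            all_posts = posts + [extra]
            ids = tuple(p.subject_id for p in all_posts)
            X = np.vstack([design.values, [[1.0]]])
            d2 = fsdcm.DesignMatrix("null", X, ("constant",), ids)
            return fsdcm.fit_peb(all_posts, d2, config=cfg).beta_mean[0]

        shift_precise = np.linalg.norm(refit_with_extra(1.0) - base)
        shift_vague = np.linalg.norm(refit_with_extra(100.0) - base)
        assert shift_vague < 0.05 * shift_precise

    def test_subject_order_mismatch_rejected(self, records):
        posts = make_posteriors(np.zeros((19, 4)))[::-1]
        design = fsdcm.build_design_matrix(records, "null")
        with pytest.raises(ValueError, match="ordering"):
            fsdcm.fit_peb(posts, design)

    def test_rank_deficient_design_rejected(self, records):
        design = fsdcm.build_design_matrix(records, "total positive")
        X = design.values.copy()
        X[:, 1] = 0.0  # degenerate covariate
        broken = fsdcm.DesignMatrix(design.name, X, design.columns,
                                    design.subject_ids)
        posts = make_posteriors(np.zeros((19, 4)))
        with pytest.raises(ValueError, match="rank"):
            fsdcm.fit_peb(posts, broken)

    def test_null_truth_selects_null_and_effect_truth_selects_covariate(self):
        records = fsdcm.generate_clinical(19, seed=9)
        rng = np.random.default_rng(10)
        design_tp = fsdcm.build_design_matrix(records, "total positive")

        def comparison_for(beta_cov_effect):
            beta = np.zeros((4, 4))
            beta[1] = beta_cov_effect
            thetas = design_tp.values @ beta \
                + 0.05 * rng.standard_normal((19, 4))
            posts = make_posteriors(thetas, cov=np.eye(4) * 0.01)
            models = [fsdcm.fit_peb(
                posts, fsdcm.build_design_matrix(records, name))
                for name in fsdcm.MODEL_LABELS]
            return fsdcm.compare_models(models)

        null_cmp = comparison_for(np.zeros(4))
        assert null_cmp.best == "null"
        effect_cmp = comparison_for(np.array([0.1, -0.1, -0.1, 0.1]))
        assert effect_cmp.best == "total positive"
        assert effect_cmp.posterior_probs.max() > 0.95


class TestModelComparison:
    def test_published_style_two_model_bayes_factor(self):
        cmp = fsdcm.compare_free_energies(
            ["total positive", "delusions"], [-5961.0, -5966.0])
        assert cmp.ln_bf == pytest.approx([0.0, -5.0])
        assert cmp.posterior_probs == pytest.approx([0.99331, 0.00669],
                                                    abs=1e-5)

    def test_equal_evidence_splits_evenly(self):
        cmp = fsdcm.compare_free_energies(["a", "b"], [-10.0, -10.0])
        assert cmp.posterior_probs == pytest.approx([0.5, 0.5])

    def test_bf_20_gives_pp_just_above_selection_threshold(self):
        cmp = fsdcm.compare_free_energies(["win", "lose"],
                                          [0.0, -np.log(20.0)])
        assert cmp.posterior_probs[0] == pytest.approx(20.0 / 21.0, abs=1e-12)
        assert cmp.posterior_probs[0] > 0.95

    def test_nine_published_free_energies(self):
        table = fsdcm.packaged_group_free_energies()
        cmp = fsdcm.compare_free_energies(table.model, table.free_energy)
        assert cmp.posterior_probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert cmp.best == "total positive"
        assert cmp.ln_bf[list(cmp.names).index("total positive")] == 0.0

    def test_adding_a_model_only_renormalizes(self):
        table = fsdcm.packaged_group_free_energies()
        full = fsdcm.compare_free_energies(table.model, table.free_energy)
        sub = fsdcm.compare_free_energies(table.model[:8], table.free_energy[:8])
        # evidence ratios between shared models are unchanged
        r_full = full.posterior_probs[0] / full.posterior_probs[1]
        r_sub = sub.posterior_probs[0] / sub.posterior_probs[1]
        assert r_full == pytest.approx(r_sub, rel=1e-10)

    def test_fewer_than_two_models_rejected(self):
        with pytest.raises(ValueError, match="two models"):
            fsdcm.compare_free_energies(["only"], [-5.0])


class TestEffectProbabilities:
    def _toy_model(self, effect, post_sd, records):
        design = fsdcm.build_design_matrix(records, "delusions")
        k = design.values.shape[1]
        beta = np.zeros((k, 4))
        beta[1, :] = effect
        cov = np.eye(4 * k) * post_sd ** 2
        prior = np.full(4 * k, 0.04)
        return fsdcm.PEBModel(
            name="delusions", design=design, beta_mean=beta,
            beta_covariance=cov, random_effect_precision=np.full(4, 16.0),
            free_energy=0.0, beta_prior_diag=prior)

    def test_five_sigma_effect_is_near_certain(self, records):
        model = self._toy_model(effect=0.1, post_sd=0.02, records=records)
        for e in fsdcm.effect_probabilities(model):
            assert e.posterior_prob > 0.99
            assert e.direction == 1

    def test_zero_effect_is_at_most_even_odds(self, records):
        model = self._toy_model(effect=0.0, post_sd=0.02, records=records)
        for e in fsdcm.effect_probabilities(model):
            assert e.posterior_prob <= 0.5

    def test_null_model_has_no_covariate(self, records):
        design = fsdcm.build_design_matrix(records, "null")
        model = fsdcm.PEBModel(
            name="null", design=design, beta_mean=np.zeros((1, 4)),
            beta_covariance=np.eye(4) * 0.01,
            random_effect_precision=np.full(4, 16.0), free_energy=0.0,
            beta_prior_diag=np.full(4, 1 / 16))
        with pytest.raises(ValueError, match="covariate"):
            fsdcm.effect_probabilities(model)
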