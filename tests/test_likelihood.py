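"""Likelihood, MLE fitting, covariance and Wald tests."""

import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from triadpower import DesignSpec, EffectSpec, LocusSpec
from triadpower.likelihood import (
    build_contrasts,
    build_design_model,
    category_probs,
    counts_to_arrays,
    fit_mle,
    loglik,
    true_params,
    wald,
)
from triadpower.triad_model import case_probs, control_probs, enumerate_cells, marginalize

from conftest import make_effect


def expected_counts(locus, effect, design):
    """N_s * p_s(theta_true) per stratum, via the cell-table route."""
    cells = enumerate_cells(locus)
    cond = {True: case_probs(cells, effect), False: control_probs(cells)}
    out = {}
    for is_case, cfg, n in design.strata():
        table = marginalize(cond[is_case], cfg)
        out[(is_case, cfg)] = n * table.probs
    return out


class TestCategoryProbs:
    def test_matches_cell_table_at_truth(self, locus, poo_effect, triads500):
        model = build_design_model(locus, poo_effect, triads500)
        theta = true_params(locus, poo_effect)
        p = category_probs(theta, model, model.strata[0])
        direct = marginalize(case_probs(enumerate_cells(locus), poo_effect), "mfc")
        np.testing.assert_allclose(p, direct.probs, atol=1e-14)

    def test_control_stratum_ignores_effect_parameters(self, locus, child_effect):
        design = DesignSpec({"mfc": 100}, {"mfc": 100})
        model = build_design_model(locus, child_effect, design)
        theta = true_params(locus, child_effect)
        ctrl = next(s for s in model.strata if not s.is_case)
        p = category_probs(theta, model, ctrl)
        null_direct = marginalize(control_probs(enumerate_cells(locus)), "mfc")
        np.testing.assert_allclose(p, null_direct.probs, atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_probabilities_valid_for_random_parameters(self, locus, poo_effect,
                                                       triads500, seed):
        rng = np.random.default_rng(seed)
        model = build_design_model(locus, poo_effect, triads500)
        theta = rng.normal(scale=1.5, size=model.layout.n_params)
        p = category_probs(theta, model, model.strata[0])
        assert np.all(p > 0) and np.all(p < 1)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gradient_matches_finite_differences(self, locus):
        effect = make_effect("poo+maternal", rr_poo_m=(1, 2), rr_poo_f=(1, 1.5),
                             rr_maternal=(1, 1.2))
        design = DesignSpec({"mfc": 300, "mc": 200}, {"mc": 100})
        model = build_design_model(locus, effect, design)
        rng = np.random.default_rng(7)
        counts = {(s.is_case, s.configuration):
                  rng.integers(0, 20, size=len(s.categories)).astype(float)
                  for s in model.strata}
        theta = rng.normal(scale=0.4, size=model.layout.n_params)
        _ll, grad = loglik(theta, model, counts, with_grad=True)
        h = 1e-6
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = h
            fd = (loglik(theta + e, model, counts) -
                  loglik(theta - e, model, counts)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestLoglik:
    def test_zero_counts_give_zero(self, locus, child_effect, triads500):
        model = build_design_model(locus, child_effect, triads500)
        counts = {(True, "mfc"): np.zeros(15)}
        assert loglik(true_params(locus, child_effect), model, counts) == 0.0

    def test_matches_multinomial_logpmf_up_to_constant(self, locus, child_effect,
                                                       triads500):
        model = build_design_model(locus, child_effect, triads500)
        theta = true_params(locus, child_effect)
        p = category_probs(theta, model, model.strata[0])
        rng = np.random.default_rng(0)
        n = rng.multinomial(500, p).astype(float)
        ll = loglik(theta, model, {(True, "mfc"): n})
        logpmf = stats.multinomial.logpmf(n, 500, p)
        log_coeff = logpmf - (n @ np.log(p))
        assert ll == pytest.approx(logpmf - log_coeff, rel=1e-12)

    def test_truth_maximizes_expected_loglik(self, locus, poo_effect, triads500):
        # Gibbs' inequality: E_theta0[log p_theta] is maximized at theta0.
        model = build_design_model(locus, poo_effect, triads500)
        theta0 = true_params(locus, poo_effect)
        counts = expected_counts(locus, poo_effect, triads500)
        counts = {k: np.asarray(v) for k, v in counts.items()}
        ll0 = loglik(theta0, model, counts)
        rng = np.random.default_rng(42)
        for _ in range(20):
            ll = loglik(theta0 + rng.normal(scale=0.3, size=theta0.size),
                        model, counts)
            assert ll < ll0


class TestFit:
    def test_recovers_truth_from_expected_counts(self, locus):
        effect = make_effect("poo+maternal", rr_poo_m=(1, 2), rr_poo_f=(1, 1.5),
                             rr_maternal=(1, 1.2))
        design = DesignSpec({"mfc": 500}, {"mfc": 500})
        counts = expected_counts(locus, effect, design)
        fit = fit_mle(counts, effect, design, locus)
        assert fit.converged
        np.testing.assert_allclose(fit.estimates, true_params(locus, effect),
                                   atol=1e-4)

    def test_case_control_mle_equals_allele_count_odds_ratio(self, locus):
        # In a c-c child-model design the case children are HWE with tilted
        # allele frequencies, so the MLE of RR is the allele-based odds
        # ratio between case and control children (closed form).
        effect = make_effect("child", rr_child=(1, 1.4))
        design = DesignSpec({"c": 400}, {"c": 600})
        counts = {
            (True, "c"): {((0, 0),): 150, ((0, 1),): 180, ((1, 1),): 70},
            (False, "c"): {((0, 0),): 350, ((0, 1),): 200, ((1, 1),): 50},
        }
        fit = fit_mle(counts, effect, design, locus)
        case1 = 2 * 150 + 180
        case2 = 2 * 70 + 180
        ctrl1 = 2 * 350 + 200
        ctrl2 = 2 * 50 + 200
        odds_ratio = (case2 / case1) / (ctrl2 / ctrl1)
        assert np.exp(fit.estimate("RR:2")) == pytest.approx(odds_ratio, rel=1e-6)

    def test_optimum_beats_coarse_grid(self, locus, child_effect, triads500):
        model = build_design_model(locus, child_effect, triads500)
        rng = np.random.default_rng(3)
        p = category_probs(true_params(locus, child_effect), model, model.strata[0])
        counts = {(True, "mfc"): rng.multinomial(500, p).astype(float)}
        fit = fit_mle(counts, child_effect, triads500, locus)
        grid = np.arange(-1.0, 1.0, 0.01)
        best_grid = max(loglik(np.array([b, r]), model, counts)
                        for b, r in itertools.product(grid, grid))
        assert fit.loglik >= best_grid - 1e-9

    def test_mc_poo_maternal_rejected_as_overparameterized(self, locus):
        effect = make_effect("poo+maternal", rr_poo_m=(1, 2), rr_poo_f=(1, 1.5),
                             rr_maternal=(1, 1.2))
        with pytest.raises(ValueError, match="overparameterized"):
            build_design_model(locus, effect, DesignSpec({"mc": 500}))

    def test_em_fixed_point_matches_direct_optimum(self, locus, poo_effect,
                                                   triads500):
        # EM resolves origin ambiguity explicitly: E-step splits category
        # counts over member cells, M-step maximizes the complete-data
        # likelihood.  Its fixed point must equal the direct optimum of the
        # summed (observed-data) likelihood.
        model = build_design_model(locus, poo_effect, triads500)
        stratum = model.strata[0]
        rng = np.random.default_rng(11)
        p_true = category_probs(true_params(locus, poo_effect), model, stratum)
        counts = {(True, "mfc"): rng.multinomial(200, p_true).astype(float)}
        direct = fit_mle(counts, poo_effect, triads500, locus)

        nonref = locus.nonref_indices
        theta = np.zeros(model.layout.n_params)
        for _ in range(200):
            pi = stratum.cell_probs(theta, model.layout, nonref,
                                    locus.reference_index)
            p_cat = stratum.M @ pi
            # E-step: expected cell counts given observed category counts
            weights = stratum.M.T @ (counts[(True, "mfc")] / p_cat) * pi

            def complete_nll(t):
                pi_t = stratum.cell_probs(t, model.layout, nonref,
                                          locus.reference_index)
                return -(weights @ np.log(pi_t))

            theta = optimize.minimize(complete_nll, theta, method="Nelder-Mead",
                                      options={"xatol": 1e-12, "fatol": 1e-14,
                                               "maxiter": 5000}).x
        np.testing.assert_allclose(theta, direct.estimates, atol=1e-6)

    def test_parameter_recovery_and_covariance_at_n2000(self, locus, child_effect):
        # Across replicates at N=2000: median log-RR bias within Monte-Carlo
        # error of zero, and the mean reported covariance close to the
        # empirical covariance of the estimates.
        design = DesignSpec({"mfc": 2000})
        model = build_design_model(locus, child_effect, design)
        theta0 = true_params(locus, child_effect)
        p = category_probs(theta0, model, model.strata[0])
        rng = np.random.default_rng(19)
        n_rep = 500  # keeps the empirical covariance's own noise well below 15%
        estimates, covariances = [], []
        for _ in range(n_rep):
            counts = {(True, "mfc"): rng.multinomial(2000, p).astype(float)}
            fit = fit_mle(counts, child_effect, design, model=model)
            assert fit.converged
            estimates.append(fit.estimates)
            covariances.append(fit.covariance)
        estimates = np.array(estimates)
        idx = model.layout.index("RR:2")
        bias = np.median(estimates[:, idx]) - theta0[idx]
        mc_err = 1.2533 * estimates[:, idx].std(ddof=1) / np.sqrt(n_rep)
        assert abs(bias) < 3 * mc_err
        emp_cov = np.cov(estimates.T)
        mean_cov = np.mean(covariances, axis=0)
        np.testing.assert_allclose(mean_cov, emp_cov, rtol=0.15)
        # the mean reported covariance should also agree with the
        # noise-free asymptotic covariance (inverse expected information)
        from triadpower import expected_information
        I, _m = expected_information(locus, child_effect, design)
        np.testing.assert_allclose(mean_cov, np.linalg.inv(I), rtol=0.02)


class TestWald:
    @pytest.fixture
    def fit(self, locus, poo_effect, triads500):
        counts = expected_counts(locus, poo_effect, triads500)
        return fit_mle(counts, poo_effect, triads500, locus)

    def test_zero_contrast_value_gives_p_one(self, fit):
        c = np.zeros(fit.layout.n_params)
        c[fit.layout.index("RRcm:2")] = 0.0
        with pytest.raises(ValueError):
            wald(fit, c)  # exactly zero contrast has zero variance

    def test_scalar_statistic_is_squared_z(self, fit):
        stat, p = wald(fit, "RRcm:2")
        z = fit.estimate("RRcm:2") / fit.se("RRcm:2")
        assert stat == pytest.approx(z ** 2, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_statistic_invariant_under_contrast_scaling(self, fit, locus,
                                                        poo_effect):
        contrasts = build_contrasts(fit.layout, poo_effect, locus)
        c = contrasts["RRcm_cf:2"]
        stat1, _ = wald(fit, c)
        stat2, _ = wald(fit, 7.3 * c)
        assert stat1 == pytest.approx(stat2, rel=1e-12)

    def test_poo_ratio_contrast_is_difference_of_logs(self, fit, locus,
                                                      poo_effect):
        contrasts = build_contrasts(fit.layout, poo_effect, locus)
        c = contrasts["RRcm_cf:2"]
        value = c @ fit.estimates
        assert value == pytest.approx(
            fit.estimate("RRcm:2") - fit.estimate("RRcf:2"), rel=1e-12)

    def test_null_parameter_gives_p_one_at_expected_counts(self, locus, triads500):
        # RRcf = 1 at the truth: the fitted contrast is ~0 and p ~ 1.
        effect = make_effect("poo", rr_poo_m=(1, 1.5), rr_poo_f=(1, 1))
        counts = expected_counts(locus, effect, triads500)
        fit = fit_mle(counts, effect, triads500, locus)
        stat, p = wald(fit, "RRcf:2")
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)
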