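"""Mixture density, composite likelihood and genetic correlation."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import multinomial, multivariate_normal

from mrci.data import SummaryDataset
from mrci.enumeration import ComponentCounts, EnumerationPlan
from mrci.likelihood import (
    LikelihoodWorkspace,
    composite_log_likelihood,
    genetic_correlation,
    marginal_covariance,
    rg_variance,
    snp_log_likelihood,
)
from mrci.params import FULL_MODEL, ModelParams


class TestMarginalCovariance:
    def test_null_composition_gives_noise_floor(self, toy_params):
        v1, v2, cv, clamped = marginal_covariance(
            ComponentCounts(0, 0, 0, 9), 3.0, 9, 1e4, 2e4, toy_params
        )
        assert v1 == pytest.approx(toy_params.a1 + 1e-4)
        assert v2 == pytest.approx(toy_params.a2 + 5e-5)
        assert cv == pytest.approx(toy_params.rho0)
        assert not clamped

    def test_no_causation_collapses_to_direct_terms(self, toy_params):
        p = toy_params.replace(delta12=0.0, delta21=0.0)
        ell, nstar = 2.5, 5
        v1, v2, cv, _ = marginal_covariance(
            ComponentCounts(2, 0, 0, 3), ell, nstar, 1e4, 2e4, p
        )
        assert v1 == pytest.approx(p.sigma1_sq * (2 / 5) * ell + p.a1 + 1e-4)
        assert v2 == pytest.approx(p.a2 + 5e-5)
        assert cv == pytest.approx(p.rho0)

    def test_label_swap_symmetry(self, toy_params):
        c = ComponentCounts(1, 2, 1, 3)
        c_sw = ComponentCounts(2, 1, 1, 3)
        v1, v2, cv, _ = marginal_covariance(c, 2.0, 7, 1e4, 2e4, toy_params)
        w2, w1, cw, _ = marginal_covariance(
            c_sw, 2.0, 7, 2e4, 1e4, toy_params.swap_traits()
        )
        assert v1 == pytest.approx(w1)
        assert v2 == pytest.approx(w2)
        assert cv == pytest.approx(cw)

    def test_matches_generative_model_monte_carlo(self, toy_params, rng):
        """Covariance formula vs direct simulation of the structural model.

        One SNP tagging 3 SNPs (one per causal component) with equal LD
        r^2; simulate joint effects, mix through LD and add noise.
        """
        p = toy_params.replace(a1=0.0, a2=0.0, rho0=0.0)
        n1 = n2 = 1e6  # tiny noise so the genetic part dominates
        nstar, ell = 3, 1.8
        r2 = ell / nstar
        rho = math.sqrt(r2)
        n_draw = 400_000
        d = np.array([[0.0, p.delta12], [p.delta21, 0.0]])
        Binv = np.linalg.inv(np.eye(2) - d)
        g1 = rng.normal(0, math.sqrt(p.sigma1_sq), n_draw)
        g2 = rng.normal(0, math.sqrt(p.sigma2_sq), n_draw)
        gc = rng.multivariate_normal(
            [0, 0],
            [[p.sigmaC1_sq, p.rhoC1C2], [p.rhoC1C2, p.sigmaC2_sq]],
            size=n_draw,
        )
        # beta for the three tagged SNPs, summed with LD weight rho each
        beta = (
            Binv @ np.vstack([g1, np.zeros(n_draw)])
            + Binv @ np.vstack([np.zeros(n_draw), g2])
            + Binv @ gc.T
        )
        tau = rho * beta
        emp = np.cov(tau)
        v1, v2, cv, _ = marginal_covariance(
            ComponentCounts(1, 1, 1, 0), ell, nstar, n1, n2, p
        )
        mc_se = 3 / math.sqrt(n_draw)
        assert emp[0, 0] == pytest.approx(v1 - 1 / n1, rel=5 * mc_se)
        assert emp[1, 1] == pytest.approx(v2 - 1 / n2, rel=5 * mc_se)
        assert emp[0, 1] == pytest.approx(cv, rel=8 * mc_se)


def _brute_force_loglik(record, params, n1, n2):
    """Independent oracle: exhaustive composition sum via scipy."""
    total = 0.0
    nstar = record.n_tagged
    pvec = [params.pi1, params.pi2, params.piC, params.pi0]
    for a, b, c in itertools.product(range(nstar + 1), repeat=3):
        if a + b + c > nstar:
            continue
        counts = ComponentCounts(a, b, c, nstar - a - b - c)
        prior = multinomial.pmf([a, b, c, nstar - a - b - c], n=nstar, p=pvec)
        if prior == 0:
            continue
        v1, v2, cv, _ = marginal_covariance(
            counts, record.ld_score, nstar, n1, n2, params
        )
        dens = multivariate_normal.pdf(
            [record.tau1_hat, record.tau2_hat],
            mean=[0, 0],
            cov=[[v1 + 1e-12, cv], [cv, v2 + 1e-12]],
        )
        total += prior * dens
    return math.log(total)


class TestSnpLogLikelihood:
    def test_single_term_mixture_when_pis_zero(self, tiny_dataset):
        p = ModelParams(a1=1e-4, a2=2e-4, rho0=1e-5)
        plan = EnumerationPlan.for_dataset(tiny_dataset)
        rec = tiny_dataset.record(3)
        got = snp_log_likelihood(rec, p, plan, tiny_dataset.n1, tiny_dataset.n2)
        v1 = p.a1 + 1 / tiny_dataset.n1
        v2 = p.a2 + 1 / tiny_dataset.n2
        expected = multivariate_normal.logpdf(
            [rec.tau1_hat, rec.tau2_hat],
            cov=[[v1 + 1e-12, p.rho0], [p.rho0, v2 + 1e-12]],
        )
        assert got == pytest.approx(float(expected), abs=1e-9)

    def test_equals_exhaustive_enumeration(self, tiny_dataset, toy_params):
        """No truncation: must match the brute-force oracle to 1e-10."""
        p = toy_params.replace(pi1=0.05, pi2=0.05, piC=0.05)
        plan = EnumerationPlan.for_dataset(tiny_dataset, c_max=5, c_total=5)
        for k in range(tiny_dataset.K):
            rec = tiny_dataset.record(k)
            got = snp_log_likelihood(rec, p, plan, tiny_dataset.n1, tiny_dataset.n2)
            want = _brute_force_loglik(rec, p, tiny_dataset.n1, tiny_dataset.n2)
            assert got == pytest.approx(want, abs=1e-10)

    def test_phenotype_label_swap_invariance(self, tiny_dataset, toy_params):
        plan = EnumerationPlan.for_dataset(tiny_dataset)
        swapped = tiny_dataset.swap_traits()
        ps = toy_params.swap_traits()
        for k in range(tiny_dataset.K):
            a = snp_log_likelihood(
                tiny_dataset.record(k), toy_params, plan,
                tiny_dataset.n1, tiny_dataset.n2,
            )
            b = snp_log_likelihood(
                swapped.record(k), ps, plan, swapped.n1, swapped.n2
            )
            assert a == pytest.approx(b, rel=1e-12)

    def test_extreme_effects_stay_finite(self, tiny_dataset, toy_params):
        """Densities near exp(-700) must not underflow to -inf."""
        d = SummaryDataset(
            tiny_dataset.snp_ids,
            np.full(5, 0.1),
            np.full(5, -0.1),
            tiny_dataset.ld_score,
            tiny_dataset.adjacency,
            30_000,
            30_000,
        )
        p = ModelParams(a1=1e-9, a2=1e-9)
        plan = EnumerationPlan.for_dataset(d)
        ll = snp_log_likelihood(d.record(4), p, plan, d.n1, d.n2)
        assert np.isfinite(ll)
        assert ll < -100


class TestCompositeLikelihood:
    def test_single_snp_equals_member(self, tiny_dataset, toy_params):
        sub = tiny_dataset.subset([3])
        plan = EnumerationPlan.for_dataset(sub)
        cl = composite_log_likelihood(sub, toy_params, plan)
        member = snp_log_likelihood(sub.record(0), toy_params, plan, sub.n1, sub.n2)
        assert cl == pytest.approx(member)

    def test_duplication_doubles_cl(self, tiny_dataset, toy_params):
        import scipy.sparse as sp

        dup = SummaryDataset(
            [f"c{i}" for i in range(10)],
            np.tile(tiny_dataset.tau1, 2),
            np.tile(tiny_dataset.tau2, 2),
            np.tile(tiny_dataset.ld_score, 2),
            sp.block_diag([tiny_dataset.adjacency] * 2, format="csr"),
            tiny_dataset.n1,
            tiny_dataset.n2,
        )
        plan = EnumerationPlan.for_dataset(tiny_dataset)
        plan_dup = EnumerationPlan.for_dataset(dup)
        cl1 = composite_log_likelihood(tiny_dataset, toy_params, plan)
        cl2 = composite_log_likelihood(dup, toy_params, plan_dup)
        assert cl2 == pytest.approx(2 * cl1, rel=1e-12)

    def test_workspace_matches_scalar_reference(self, small_sim, toy_params):
        data, truth = small_sim
        params = truth["params"]
        plan = EnumerationPlan.for_dataset(data)
        ws = LikelihoodWorkspace(data, plan)
        ll = ws.loglik_per_snp(params)
        for k in (0, 17, 555, data.K - 1):
            ref = snp_log_likelihood(data.record(k), params, plan, data.n1, data.n2)
            assert ll[k] == pytest.approx(ref, abs=1e-9)

    def test_true_model_beats_zeroed_causation(self, small_sim):
        data, truth = small_sim
        params = truth["params"]
        plan = EnumerationPlan.for_dataset(data)
        ws = LikelihoodWorkspace(data, plan)
        assert ws.cl(params) > ws.cl(params.replace(delta12=0.0, delta21=0.0))


class TestGeneticCorrelation:
    def test_zero_without_causation_or_pleiotropy_corr(self, toy_params):
        p = toy_params.replace(delta12=0.0, delta21=0.0, rhoC1C2=0.0)
        assert genetic_correlation(p) == 0.0

    def test_unity_for_perfectly_correlated_pleiotropy_only(self):
        p = ModelParams(
            piC=0.01, sigmaC1_sq=0.3, sigmaC2_sq=0.3, rhoC1C2=0.3
        )
        assert genetic_correlation(p) == pytest.approx(1.0)

    def test_bounded_on_admissible_set(self, rng):
        from mrci.params import ParamTransform

        t = ParamTransform(FULL_MODEL.free_names)
        for _ in range(50):
            z = rng.normal(0, 2, t.n)
            p = t.to_params(z, ModelParams())
            try:
                rg = genetic_correlation(p)
            except ValueError:
                continue
            assert -1.0 <= rg <= 1.0

    def test_zero_genetic_variance_is_an_error(self):
        with pytest.raises(ValueError):
            genetic_correlation(ModelParams(pi1=0.1, sigma1_sq=0.1))


class TestRgVariance:
    def test_zero_covariance_gives_zero(self, toy_params):
        cov = np.zeros((13, 13))
        assert rg_variance(toy_params, cov, FULL_MODEL.free_names) == 0.0

    def test_single_free_parameter_matches_scalar_delta_method(self, toy_params):
        names = FULL_MODEL.free_names
        j = names.index("delta12")
        cov = np.zeros((13, 13))
        cov[j, j] = 0.01
        got = rg_variance(toy_params, cov, names)
        h = 1e-5 * max(abs(toy_params.delta12), 1e-3)
        up = genetic_correlation(toy_params.replace(delta12=toy_params.delta12 + h))
        dn = genetic_correlation(toy_params.replace(delta12=toy_params.delta12 - h))
        grad = (up - dn) / (2 * h)
        assert got == pytest.approx(grad**2 * 0.01, rel=1e-6)

    def test_step_halving_changes_result_quadratically(self, toy_params):
        cov = np.eye(13) * 1e-4
        names = FULL_MODEL.free_names
        v1 = rg_variance(toy_params, cov, names, h=1e-3)
        v2 = rg_variance(toy_params, cov, names, h=5e-4)
        v3 = rg_variance(toy_params, cov, names, h=2.5e-4)
        assert abs(v2 - v3) <= abs(v1 - v2) + 1e-12
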