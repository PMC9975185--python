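"""Synthetic-data generator: LD structure, effects, and both simulation
levels."""

import math

import numpy as np
import pytest

from mrci.simulate import (
    G1,
    G2,
    GC,
    NULL,
    SCENARIO_NAMES,
    SimulationScenario,
    assign_components_and_effects,
    build_ld_structure,
    direct_to_joint,
    scenario,
    simulate_individual_level,
    simulate_marginal_estimates,
    simulate_summary_dataset,
)


class TestLdStructure:
    def test_no_ld_when_blocks_are_singletons(self):
        scn = scenario("his-bi", M=1000, block_size=1)
        ld = build_ld_structure(scn)
        assert np.allclose(ld.reference.ld_score, 1.0)
        assert np.all(ld.reference.n_tagged == 1)

    def test_middle_snp_ld_score_by_hand(self):
        scn = SimulationScenario(M=3, block_size=3, ar1_r=0.9, pi1=1.0,
                                 pi2=0.0, piC=0.0, h2_2spec=0.0, h2_pleio=0.0,
                                 pleiotropy_corr=0.0, delta12=0.0, delta21=0.0)
        ld = build_ld_structure(scn)
        assert ld.reference.ld_score[1] == pytest.approx(0.81 + 1 + 0.81)

    def test_ld_score_never_exceeds_tag_count(self):
        scn = scenario("his-bi", M=1000, block_size=25)
        ld = build_ld_structure(scn)
        assert np.all(ld.reference.ld_score <= ld.reference.n_tagged + 1e-9)

    def test_tagging_symmetric_and_reflexive(self):
        scn = scenario("his-bi", M=1000, block_size=10)
        adj = build_ld_structure(scn).reference.adjacency
        assert (adj != adj.T).nnz == 0
        assert np.all(adj.diagonal() == 1)


class TestEffects:
    def test_zero_pis_give_all_null(self, rng):
        scn = SimulationScenario(M=200, pi1=0, pi2=0, piC=0, h2_1spec=0,
                                 h2_2spec=0, h2_pleio=0, pleiotropy_corr=0)
        labels, g1, g2 = assign_components_and_effects(scn, rng)
        assert np.all(labels == NULL)
        assert not g1.any() and not g2.any()

    def test_exact_causal_counts(self, rng):
        scn = scenario("his-bi", M=10_000)
        labels, _, _ = assign_components_and_effects(scn, rng)
        assert (labels == G1).sum() == 10
        assert (labels == G2).sum() == 10
        assert (labels == GC).sum() == 10

    def test_component_heritability_is_exact(self, rng):
        scn = scenario("his-bi", M=10_000)
        labels, g1, g2 = assign_components_and_effects(scn, rng)
        assert (g1[labels == G1] ** 2).sum() == pytest.approx(0.3)
        assert (g2[labels == G2] ** 2).sum() == pytest.approx(0.3)
        assert (g1[labels == GC] ** 2).sum() == pytest.approx(0.1)
        assert (g2[labels == GC] ** 2).sum() == pytest.approx(0.1)

    def test_pleiotropy_correlation_is_pinned_exactly(self, rng):
        scn = scenario("his-bi", M=10_000)
        labels, g1, g2 = assign_components_and_effects(scn, rng)
        ic = labels == GC
        cos = (g1[ic] @ g2[ic]) / np.sqrt(
            (g1[ic] @ g1[ic]) * (g2[ic] @ g2[ic])
        )
        assert cos == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_pleiotropy_correlation(self, rng):
        scn = scenario("his-bi", M=20_000, pleiotropy_corr=1.0)
        labels, g1, g2 = assign_components_and_effects(scn, rng)
        ic = labels == GC
        r = np.corrcoef(g1[ic], g2[ic])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_effect_variance_matches_large_sample(self, rng):
        """Per-SNP variance of drawn gamma over many causal SNPs ~ sigma^2."""
        scn = SimulationScenario(M=100_000, pi1=0.1, pi2=0, piC=0,
                                 h2_1spec=0.3, h2_2spec=0, h2_pleio=0,
                                 pleiotropy_corr=0, delta12=0, delta21=0)
        labels, g1, _ = assign_components_and_effects(scn, rng)
        v = g1[labels == G1].var()
        assert v == pytest.approx(scn.sigma1_sq, rel=0.05)


class TestDirectToJoint:
    def test_identity_when_no_causation(self):
        b1, b2 = direct_to_joint([1.0, 2.0], [3.0, 4.0], 0.0, 0.0)
        assert np.allclose(b1, [1, 2])
        assert np.allclose(b2, [3, 4])

    def test_hand_solved_two_by_two(self):
        b1, b2 = direct_to_joint([1.0], [0.0], 0.0, 0.5)
        assert b1[0] == pytest.approx(1.0)
        assert b2[0] == pytest.approx(0.5)

    def test_no_path_without_delta12(self):
        # a trait-2-specific SNP cannot reach Y1 when delta12 = 0
        b1, _ = direct_to_joint([0.0], [1.0], 0.0, 0.3)
        assert b1[0] == 0.0

    def test_explosive_feedback_rejected(self):
        with pytest.raises(ValueError):
            direct_to_joint([1.0], [1.0], 1.5, 0.9)


class TestSummaryLevel:
    def test_pure_noise_variance(self, rng):
        scn = SimulationScenario(
            M=20_000, n1=10_000, n2=10_000, pi1=0, pi2=0, piC=0,
            h2_1spec=0, h2_2spec=0, h2_pleio=0, pleiotropy_corr=0,
            delta12=0, delta21=0, block_size=1, overlap_fraction=0,
        )
        ld = build_ld_structure(scn)
        data = simulate_marginal_estimates(
            scn, ld, np.zeros(scn.M), np.zeros(scn.M), rng
        )
        assert data.tau1.var() == pytest.approx(1e-4, rel=0.05)

    def test_overlap_induces_cross_trait_noise_correlation(self, rng):
        scn = SimulationScenario(
            M=20_000, n1=2_000, n2=2_000, pi1=0, pi2=0, piC=1e-3,
            h2_1spec=0, h2_2spec=0, h2_pleio=0.3, pleiotropy_corr=0.9,
            delta12=0.2, delta21=0.2, block_size=1, overlap_fraction=1.0,
        )
        ld = build_ld_structure(scn)
        data = simulate_marginal_estimates(
            scn, ld, np.zeros(scn.M), np.zeros(scn.M), rng
        )
        emp = np.mean(data.tau1 * data.tau2)
        se = np.sqrt(1.0 / scn.n1 / scn.n2 / scn.M)
        assert emp == pytest.approx(scn.rho0, abs=4 * se)

    def test_byte_identical_under_seed(self):
        scn = scenario("his-bi", M=1000)
        d1, t1 = simulate_summary_dataset(scn, seed=42)
        d2, t2 = simulate_summary_dataset(scn, seed=42)
        assert np.array_equal(d1.tau1, d2.tau1)
        assert np.array_equal(d1.tau2, d2.tau2)
        assert t1["params"] == t2["params"]

    def test_unknown_scenario_lists_presets(self):
        with pytest.raises(KeyError, match="available"):
            scenario("nope")
        assert "his-bi" in SCENARIO_NAMES


class TestIndividualLevel:
    def test_scale_limits_enforced(self):
        with pytest.raises(ValueError):
            simulate_individual_level(scenario("his-bi"))

    def test_zero_effects_noise_floor(self):
        scn = SimulationScenario(
            M=300, n1=2_000, n2=2_000, pi1=0, pi2=0, piC=0,
            h2_1spec=0, h2_2spec=0, h2_pleio=0, pleiotropy_corr=0,
            delta12=0, delta21=0, block_size=1,
        )
        out = simulate_individual_level(scn, seed=9)
        assert out["tau1_hat"].var() == pytest.approx(1 / 2000, rel=0.2)

    def test_single_causal_snp_recovers_beta(self):
        scn = SimulationScenario(
            M=50, n1=4_000, n2=4_000, pi1=0.02, pi2=0, piC=0,
            h2_1spec=0.3, h2_2spec=0, h2_pleio=0, pleiotropy_corr=0,
            delta12=0, delta21=0.4, block_size=1,
        )
        out = simulate_individual_level(scn, seed=13)
        k = int(np.flatnonzero(out["beta1"])[0])
        se = 1 / math.sqrt(4000)
        assert out["tau1_hat"][k] == pytest.approx(out["beta1"][k], abs=3 * se)
        # the causal path Y1 -> Y2 shows at the same SNP
        assert out["tau2_hat"][k] == pytest.approx(out["beta2"][k], abs=3 * se)

    def test_cross_generator_consistency(self):
        """Summary-level and individual-level generators agree in per-SNP
        mean and variance on a matched low-LD scenario."""
        scn = SimulationScenario(
            M=500, n1=3_000, n2=3_000, pi1=0.02, pi2=0.02, piC=0.02,
            h2_1spec=0.2, h2_2spec=0.2, h2_pleio=0.1, pleiotropy_corr=0.5,
            delta12=0.1, delta21=0.05, block_size=1,
        )
        n_rep = 40
        ind_t1 = []
        sum_t1 = []
        rng = np.random.default_rng(5)
        ld = build_ld_structure(scn)
        ind = simulate_individual_level(scn, seed=21)
        for rep in range(n_rep):
            d = simulate_marginal_estimates(
                scn, ld, ind["beta1"], ind["beta2"], rng
            )
            sum_t1.append(d.tau1)
        sum_t1 = np.array(sum_t1)
        # per-SNP mean of summary-level draws ~ tau = beta (no LD), which the
        # individual-level estimates should track within sampling error
        mean_sum = sum_t1.mean(axis=0)
        resid = ind["tau1_hat"] - mean_sum
        assert resid.std() == pytest.approx(1 / math.sqrt(scn.n1), rel=0.25)
        assert abs(resid.mean()) < 3 / math.sqrt(scn.n1 * scn.M)


class TestScenarioBookkeeping:
    def test_derived_sigma_from_heritability(self):
        scn = scenario("his-bi")
        assert scn.sigma1_sq == pytest.approx(0.3 / (1e-3 * 30_000))
        assert scn.rhoC1C2 == pytest.approx(0.1 * scn.sigmaC1_sq)

    def test_phenotypic_covariance_unit_diagonal(self):
        cov = scenario("his-bi").phenotypic_covariance()
        assert np.allclose(np.diag(cov), 1.0)

    def test_excessive_heritability_rejected(self):
        scn = scenario("his-bi", h2_1spec=0.9, h2_2spec=0.9, h2_pleio=0.3)
        with pytest.raises(ValueError):
            scn.phenotypic_covariance()

    def test_overlap_scales_rho0_linearly(self):
        full = scenario("his-bi", overlap_fraction=1.0).rho0
        half = scenario("his-bi", overlap_fraction=0.5).rho0
        none = scenario("his-bi", overlap_fraction=0.0).rho0
        assert half == pytest.approx(0.5 * full)
        assert none == 0.0
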