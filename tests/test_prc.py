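import numpy as np
import pandas as pd
import pytest

from prcnet import (
    KnockoutScreen,
    NoiseRatios,
    classify_link_inferability,
    ppca_decompose,
    prc_max_strength,
    prc_min_strength,
    prc_row_single_unperturbed,
    sample_covariance,
)
from prcnet.prc import PRCError
from prcnet import datagen
from prcnet.datasets import PerturbationDesign
from prcnet.benchmarks import sigma_invariance_deviation

from conftest import random_weighted_net


def screen_from_matrix(Y, perturbed=None):
    genes = [f"g{i}" for i in range(Y.shape[0])]
    samples = [f"s{j}" for j in range(Y.shape[1])]
    perturbed = perturbed or {}
    return KnockoutScreen(
        values=pd.DataFrame(Y, index=genes, columns=samples),
        perturbed=pd.Series({s: perturbed.get(s, np.nan) for s in samples}, dtype=object),
        replicate=pd.Series({s: 0 for s in samples}),
    )


class TestSampleCovariance:
    def test_hand_computed_two_sample_case(self):
        cov = sample_covariance(np.array([[0.0, 2.0], [0.0, 2.0]]))
        # unbiased 1/(P-1) scaling around the sample mean; regularisation
        # fires (rank 1 < 2) so the raw matrix is shrunk towards I
        raw = np.array([[2.0, 2.0], [2.0, 2.0]])
        assert cov.regularised
        np.testing.assert_allclose(cov.S, 0.95 * raw + 0.05 * np.eye(2), atol=1e-12)

    def test_constant_data_gives_identity_scaled(self):
        cov = sample_covariance(np.ones((3, 5)))
        np.testing.assert_allclose(cov.S, 0.05 * np.eye(3), atol=1e-12)

    def test_full_rank_data_not_regularised(self):
        rng = np.random.default_rng(0)
        cov = sample_covariance(rng.standard_normal((4, 50)))
        assert not cov.regularised

    def test_needs_two_samples(self):
        with pytest.raises(PRCError):
            sample_covariance(np.zeros((3, 1)))


class TestPPCA:
    def test_diagonal_worked_example(self):
        dec = ppca_decompose(np.diag([4.0, 1.0]), N0=1)
        np.testing.assert_allclose(dec.eigenvalues, [1.0, 4.0])
        assert dec.sigma2_hat == pytest.approx(1.0)
        np.testing.assert_allclose(dec.Sigma_hat, [0.0, np.sqrt(3.0)], atol=1e-12)

    def test_pure_noise_case(self):
        s2 = 0.7
        dec = ppca_decompose(s2 * np.eye(4), N0=3)
        assert dec.sigma2_hat == pytest.approx(s2)
        np.testing.assert_allclose(dec.Sigma_hat, 0.0, atol=1e-6)

    def test_forward_construction_recovered(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        sig = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        s2 = 0.5
        S = Q @ np.diag(sig**2 + s2) @ Q.T
        dec = ppca_decompose(S, N0=2)
        assert dec.sigma2_hat == pytest.approx(s2, abs=1e-10)
        np.testing.assert_allclose(np.sort(dec.Sigma_hat), np.sort(sig), atol=1e-8)
        np.testing.assert_allclose(dec.reconstruct_whitened(), S, atol=1e-8)

    def test_invalid_N0(self):
        with pytest.raises(PRCError):
            ppca_decompose(np.eye(3), N0=3)
        with pytest.raises(PRCError):
            ppca_decompose(np.eye(3), N0=0)

    def test_anisotropic_whitening(self):
        r = np.array([4.0, 1.0])
        S = np.diag([8.0, 1.0])
        dec = ppca_decompose(S, N0=1, noise=r)
        # whitened covariance diag(2, 1): sigma2 from the smaller
        assert dec.sigma2_hat == pytest.approx(1.0)


class TestRowEstimator:
    def test_two_node_cascade_recovers_minus_a(self):
        a, b = 2.0, 1.0
        for s2 in (0.0, 1.0, 10.0):
            C = np.array([[b * b, a * b * b], [a * b * b, a * a * b * b]]) + s2 * np.eye(2)
            row = prc_row_single_unperturbed(ppca_decompose(C, N0=1), 1)
            assert row.iloc[0] == pytest.approx(a)  # A_21 with A_22 = -1
            assert row.iloc[1] == -1.0

    def test_sigma_invariance_to_1e10(self):
        assert sigma_invariance_deviation() <= 1e-10

    def test_requires_single_null_direction(self):
        dec = ppca_decompose(np.diag([1.0, 2.0, 3.0]), N0=2)
        with pytest.raises(PRCError):
            prc_row_single_unperturbed(dec, 0)

    def test_chain_row_recovery_noise_free(self, chain_screens):
        net, screens = chain_screens
        screen = screens[0.0]
        cov = sample_covariance(screen)
        row = prc_row_single_unperturbed(ppca_decompose(cov, N0=1), "G3")
        assert row.loc["G1"] == pytest.approx(0.0, abs=1e-8)
        assert row.loc["G2"] == pytest.approx(net.weights[(2, 3)], abs=1e-8)

    def test_full_recovery_all_nodes_perturbed(self):
        # cycling through targets with q=1 noise-free data recovers all of A
        net, rng = random_weighted_net(6, seed=12)
        A = datagen.build_interaction_matrix(net)
        design = PerturbationDesign.single_knockouts(
            list(range(6)), 6, n_replicates=2, rng=rng, random_strength=True
        )
        screen = datagen.simulate_linear_knockouts(net, design, sigma=0.0, seed=rng, n_wt_replicates=2)
        for i, gi in enumerate(screen.genes):
            sub = screen.drop_samples_perturbing(gi)
            cov = sample_covariance(sub)
            row = prc_row_single_unperturbed(ppca_decompose(cov, N0=1), gi)
            np.testing.assert_allclose(row.to_numpy(), A[i], atol=1e-6)


class TestMinMaxStrengths:
    def test_chain_false_link_stays_small(self, chain_screens):
        net, screens = chain_screens
        for sd, screen in screens.items():
            mn = prc_min_strength(screen, "G3", "G1")
            assert abs(mn) < 0.08, f"noise {sd}"

    def test_chain_true_link_and_total_effect(self, chain_screens):
        net, screens = chain_screens
        screen = screens[0.0]
        assert prc_min_strength(screen, "G3", "G2") > 0.05
        # the maximum (total effect through node 2) is materially nonzero
        # and carries the sign of the planted weight product
        total = net.weights[(1, 2)] * net.weights[(2, 3)]
        mx = prc_max_strength(screen, "G3", "G1")
        assert np.sign(mx) == np.sign(total)
        assert abs(mx) > 0.5 * abs(total)

    def test_sole_parent_min_equals_max(self):
        net = datagen.three_node_chain(1.1, 0.9)
        two = datagen.DirectedNetwork(nodes=[1, 2], edges={(1, 2)}, weights={(1, 2): 1.1})
        rng = np.random.default_rng(3)
        design = PerturbationDesign.single_knockouts([1], 2, n_replicates=6, rng=rng, random_strength=True)
        screen = datagen.simulate_linear_knockouts(two, design, sigma=0.01, seed=rng)
        mn = prc_min_strength(screen, "G2", "G1")
        mx = prc_max_strength(screen, "G2", "G1")
        assert mn == pytest.approx(mx, abs=1e-6)
        assert mx == pytest.approx(1.1, abs=0.05)

    def test_independent_nodes_max_near_zero(self):
        net = datagen.DirectedNetwork(nodes=[0, 1], edges=set())
        rng = np.random.default_rng(4)
        design = PerturbationDesign.single_knockouts(
            [0, 1], 2, n_replicates=100, rng=rng, random_strength=True
        )
        # distinct forces per experiment for genericity
        design.experiments = [
            (v, k, float(rng.standard_normal())) for k, (v, _, _) in enumerate(design.experiments)
        ]
        screen = datagen.simulate_linear_knockouts(net, design, sigma=0.05, seed=rng)
        assert abs(prc_max_strength(screen, "G1", "G0")) < 0.1

    def test_source_without_perturbations_rejected(self, chain_screens):
        _, screens = chain_screens
        with pytest.raises(PRCError):
            prc_min_strength(screens[0.0], "G2", "G3")  # node 3 never perturbed


class TestInferabilityClassification:
    def test_degenerate_equal_distributions_inferable(self):
        d = np.full(50, 0.8)
        assert classify_link_inferability(d, d) is True

    def test_separated_distributions_non_inferable(self):
        rng = np.random.default_rng(0)
        mn = rng.normal(0.0, 0.01, 400)
        mx = rng.normal(0.6, 0.01, 400)
        assert classify_link_inferability(mn, mx) is False

    def test_nonzero_minimum_is_inferable(self):
        rng = np.random.default_rng(1)
        mn = rng.normal(0.5, 0.01, 400)
        mx = rng.normal(0.9, 0.01, 400)
        assert classify_link_inferability(mn, mx) is True

    def test_empty_distributions_rejected(self):
        with pytest.raises(PRCError):
            classify_link_inferability(np.array([]), np.array([]))


def test_noise_ratio_validation():
    with pytest.raises(PRCError):
        NoiseRatios(pd.Series({"a": 0.0}))
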