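"""Connectivity algebra: EC <-> transfer <-> FC and spectral decomposition."""

import numpy as np
import pytest

from neuromodes.connectivity import (
    CovarianceSpectrum, DirectEC, MarginalStabilityError, TransferFunction,
    covariance_from_transfer, ec_from_covariance, ec_from_transfer,
    eigen_relations, eigendecompose_cov, infer_input, similarity,
    spectral_reconstruct, transfer_from_ec, transfer_series, weight_ec,
)
from neuromodes.domain import SpatialDomain

from conftest import random_symmetric_ec


class TestWeightEC:
    def test_zero_kernel(self, unit_domain):
        ec = weight_ec(np.zeros((10, 10)), unit_domain)
        assert np.all(ec.weighted == 0)

    def test_uniform_weights_scale_constant_kernel(self):
        dom = SpatialDomain.uniform(5, total_area=2.0)  # dS = 0.4
        ec = weight_ec(3.0 * np.ones((5, 5)), dom)
        assert np.allclose(ec.weighted, 3.0 * 0.4)

    def test_columns_scaled_by_area_elementwise(self, rng):
        K = 6
        w = rng.uniform(0.5, 2.0, K)
        dom = SpatialDomain(np.zeros((K, 1)), w)
        raw = rng.standard_normal((K, K))
        ec = weight_ec(raw, dom)
        # brute-force elementwise oracle
        for j in range(K):
            for k in range(K):
                assert ec.weighted[j, k] == raw[j, k] * w[k]

    def test_shape_mismatch_rejected(self, unit_domain):
        with pytest.raises(ValueError):
            weight_ec(np.zeros((4, 4)), unit_domain)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            SpatialDomain(np.zeros((3, 1)), np.array([1.0, 0.0, 1.0]))


class TestTransferFromEC:
    def test_zero_ec_gives_identity(self, unit_domain):
        t = transfer_from_ec(weight_ec(np.zeros((10, 10)), unit_domain))
        assert np.allclose(t.matrix, np.eye(10))

    def test_half_identity_doubles(self, unit_domain):
        t = transfer_from_ec(
            DirectEC.from_weighted(0.5 * np.eye(10), unit_domain))
        assert np.allclose(t.matrix, 2.0 * np.eye(10), atol=1e-12)

    def test_inverse_identity_and_symmetry(self, unit_domain, rng):
        raw = random_symmetric_ec(10, 0.8, rng)
        ec = weight_ec(raw, unit_domain)
        t = transfer_from_ec(ec)
        assert np.abs(t.matrix @ (np.eye(10) - ec.weighted)
                      - np.eye(10)).max() < 1e-10
        assert np.allclose(t.matrix, t.matrix.T, atol=1e-10)

    def test_matches_neumann_series_at_high_order(self, rng):
        dom = SpatialDomain.uniform(8, total_area=8.0)
        raw = random_symmetric_ec(8, 0.8, rng)
        ec = weight_ec(raw, dom)
        exact = transfer_from_ec(ec).matrix
        # residual after order m scales as rho^{m+1}/(1 - rho); order 200
        # brings a rho = 0.8 system below 1e-8
        partial = transfer_series(ec, 200).matrix
        assert np.abs(exact - partial).max() < 1e-8 * np.abs(exact).max()

    def test_marginally_stable_system_rejected(self, unit_domain):
        ec = DirectEC.from_weighted(np.eye(10), unit_domain)  # Lambda = I
        with pytest.raises(MarginalStabilityError):
            transfer_from_ec(ec)


class TestECFromTransfer:
    def test_identity_transfer_gives_zero_ec(self, unit_domain):
        t = TransferFunction(np.eye(10), unit_domain)
        assert np.abs(ec_from_transfer(t).weighted).max() < 1e-14

    def test_scalar_inverse(self, unit_domain):
        t = TransferFunction(2.0 * np.eye(10), unit_domain)
        assert np.allclose(ec_from_transfer(t).weighted, 0.5 * np.eye(10))

    def test_round_trip_recovers_ec(self, unit_domain, rng):
        raw = random_symmetric_ec(10, 0.7, rng)
        ec = weight_ec(raw, unit_domain)
        back = ec_from_transfer(transfer_from_ec(ec))
        assert np.abs(back.weighted - ec.weighted).max() < 1e-10

    def test_round_trip_nonuniform_weights(self, rng):
        K = 7
        w = rng.uniform(0.2, 1.5, K)
        dom = SpatialDomain(np.zeros((K, 1)), w)
        raw = random_symmetric_ec(K, 0.5, rng)
        ec = weight_ec(raw, dom)
        back = ec_from_transfer(transfer_from_ec(ec))
        assert np.abs(back.raw - ec.raw).max() < 1e-10


class TestTransferSeries:
    def test_order_zero_is_identity(self, unit_domain, rng):
        ec = weight_ec(random_symmetric_ec(10, 0.5, rng), unit_domain)
        assert np.allclose(transfer_series(ec, 0).matrix, np.eye(10))

    def test_first_order_partial_sum(self, unit_domain):
        ec = DirectEC.from_weighted(0.5 * np.eye(10), unit_domain)
        assert np.allclose(transfer_series(ec, 1).matrix, 1.5 * np.eye(10))

    def test_error_decreases_monotonically(self, unit_domain, rng):
        ec = weight_ec(random_symmetric_ec(10, 0.9, rng), unit_domain)
        exact = transfer_from_ec(ec).matrix
        errs = [np.linalg.norm(transfer_series(ec, m).matrix - exact)
                for m in range(0, 40, 5)]
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_divergence_warned_outside_radius(self, unit_domain, rng):
        ec = DirectEC.from_weighted(1.5 * np.eye(10), unit_domain)
        with pytest.warns(RuntimeWarning, match="radius of convergence"):
            transfer_series(ec, 3)


class TestCovariance:
    def test_identity_transfer(self, unit_domain):
        c = covariance_from_transfer(TransferFunction(np.eye(10), unit_domain))
        assert np.allclose(c.matrix, np.eye(10))

    def test_diagonal_complex_transfer(self):
        dom = SpatialDomain.uniform(2, total_area=2.0)
        t = TransferFunction(np.diag([2.0, 1j]), dom)
        c = covariance_from_transfer(t)
        assert np.allclose(c.matrix, np.diag([4.0, 1.0]))

    def test_matches_double_loop_product(self, unit_domain, rng):
        T = rng.standard_normal((10, 10)) + 1j * rng.standard_normal((10, 10))
        c = covariance_from_transfer(TransferFunction(T, unit_domain)).matrix
        oracle = np.empty((10, 10), dtype=complex)
        for i in range(10):
            for j in range(10):
                oracle[i, j] = sum(T[i, k] * np.conj(T[j, k])
                                   for k in range(10))
        assert np.abs(c - oracle).max() < 1e-12 * np.abs(oracle).max()

    def test_hermitian_psd_for_arbitrary_transfer(self, unit_domain, rng):
        for _ in range(5):
            T = rng.standard_normal((10, 10)) + 1j * rng.standard_normal((10, 10))
            c = covariance_from_transfer(
                TransferFunction(T, unit_domain)).matrix
            assert np.abs(c - c.conj().T).max() < 1e-12 * np.abs(c).max()
            ev = np.linalg.eigvalsh(c)
            assert ev.min() >= -1e-10 * ev.max()


class TestEigendecomposition:
    def test_identity_covariance_degenerate(self, unit_domain):
        c = CovarianceSpectrum(np.eye(10), unit_domain)
        basis, spec = eigendecompose_cov(c)
        assert np.allclose(spec.kappa, 1.0)
        assert basis.check_orthonormal()
        assert basis.degenerate_blocks  # flagged
        R = spectral_reconstruct(basis, spec.kappa)
        assert np.abs(R - np.eye(10)).max() < 1e-10

    def test_constructed_spectrum_recovered(self):
        dom = SpatialDomain.uniform(2, total_area=2.0)
        th = 0.3
        U = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        C = U @ np.diag([4.0, 1.0]) @ U.T
        basis, spec = eigendecompose_cov(CovarianceSpectrum(C, dom))
        assert np.allclose(spec.kappa, [4.0, 1.0])
        for j in range(2):
            overlap = abs(basis.modes[:, j] @ U[:, j])
            assert overlap == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_subspace_projector(self, rng):
        dom = SpatialDomain.uniform(4, total_area=4.0)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        C = Q @ np.diag([3.0, 2.0, 2.0, 0.5]) @ Q.T
        basis, spec = eigendecompose_cov(CovarianceSpectrum(C, dom))
        assert any(len(b) == 2 for b in basis.degenerate_blocks)
        # compare projectors, not individual vectors, inside the block
        block = [b for b in basis.degenerate_blocks if len(b) == 2][0]
        P = basis.modes[:, block] @ basis.modes[:, block].T
        P_true = Q[:, 1:3] @ Q[:, 1:3].T
        assert np.abs(P - P_true).max() < 1e-8

    def test_area_weighted_orthonormality(self, rng):
        K = 12
        w = rng.uniform(0.3, 2.0, K)
        dom = SpatialDomain(np.zeros((K, 1)), w)
        S = rng.standard_normal((K, K))
        raw = S @ S.T  # symmetric PSD kernel
        weighted = raw * w[None, :]
        basis, spec = eigendecompose_cov(CovarianceSpectrum(weighted, dom))
        assert basis.check_orthonormal()
        resid = weighted @ basis.modes - basis.modes * spec.kappa[None, :]
        assert np.abs(resid).max() < 1e-8 * np.abs(spec.kappa).max()

    def test_non_hermitian_rejected(self, unit_domain, rng):
        M = rng.standard_normal((10, 10))
        with pytest.raises(ValueError):
            CovarianceSpectrum(M, unit_domain)


class TestEigenRelations:
    @pytest.mark.parametrize("lam,theta,kappa", [
        (0.0, 1.0, 1.0),
        (0.5, 2.0, 4.0),
        (1j, (1 + 1j) / 2, 0.5),
    ])
    def test_forced_values(self, lam, theta, kappa):
        th, ka = eigen_relations(lam)
        assert th == pytest.approx(theta, abs=1e-14)
        assert ka == pytest.approx(kappa, abs=1e-14)

    def test_marginal_eigenvalue_rejected(self):
        with pytest.raises(MarginalStabilityError):
            eigen_relations(1.0)

    def test_joint_consistency_random_systems(self, rng):
        for _ in range(100):
            K = 6
            dom = SpatialDomain.uniform(K, total_area=float(K))
            raw = random_symmetric_ec(K, rng.uniform(0.1, 0.9), rng)
            ec = weight_ec(raw, dom)
            lam = np.linalg.eigvalsh(ec.weighted)
            theta, kappa = eigen_relations(lam)
            t = transfer_from_ec(ec)
            theta_direct = np.sort(np.linalg.eigvalsh(t.matrix))
            assert np.abs(np.sort(theta.real) - theta_direct).max() < 1e-10
            assert np.abs(kappa - np.abs(theta) ** 2).max() < 1e-12 * max(
                1.0, kappa.max())


class TestSpectralReconstruct:
    def test_full_reconstruction_exact(self, unit_domain, rng):
        S = rng.standard_normal((10, 10))
        C = S @ S.T
        basis, spec = eigendecompose_cov(CovarianceSpectrum(C, unit_domain))
        R = spectral_reconstruct(basis, spec.kappa)
        assert np.abs(R - C).max() < 1e-10 * np.abs(C).max()

    def test_rank_one_truncation(self, unit_domain, rng):
        S = rng.standard_normal((10, 10))
        basis, spec = eigendecompose_cov(
            CovarianceSpectrum(S @ S.T, unit_domain))
        R1 = spectral_reconstruct(basis, spec.kappa, truncation=1)
        assert np.linalg.matrix_rank(R1, tol=1e-10) == 1

    def test_error_nonincreasing_in_truncation(self, unit_domain, rng):
        S = rng.standard_normal((10, 10))
        C = S @ S.T
        basis, spec = eigendecompose_cov(CovarianceSpectrum(C, unit_domain))
        errs = [np.linalg.norm(
            spectral_reconstruct(basis, spec.kappa, truncation=j) - C)
            for j in range(1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_overlong_truncation_rejected(self, unit_domain, rng):
        S = rng.standard_normal((10, 10))
        basis, spec = eigendecompose_cov(
            CovarianceSpectrum(S @ S.T, unit_domain))
        with pytest.raises(ValueError):
            spectral_reconstruct(basis, spec.kappa, truncation=11)


class TestSimilarity:
    def test_identity(self, unit_domain):
        c = CovarianceSpectrum(np.eye(10), unit_domain)
        assert np.allclose(similarity(c), np.eye(10))

    def test_eigenvalues_squared(self):
        dom = SpatialDomain.uniform(2, total_area=2.0)
        th = 0.7
        U = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        C = U @ np.diag([2.0, 1.0]) @ U.T
        S = similarity(CovarianceSpectrum(C, dom))
        assert np.allclose(np.sort(np.linalg.eigvalsh(S)), [1.0, 4.0])

    def test_matches_quadrature_integral(self, rng):
        # dot product of FC patterns with the area-weighted measure
        K = 5
        w = rng.uniform(0.5, 1.5, K)
        dom = SpatialDomain(np.zeros((K, 1)), w)
        S0 = rng.standard_normal((K, K))
        raw = S0 @ S0.T
        weighted = raw * w[None, :]
        S = similarity(CovarianceSpectrum(weighted, dom))
        oracle_raw = np.empty((K, K))
        for i in range(K):
            for j in range(K):
                oracle_raw[i, j] = np.sum(raw[i, :] * raw[:, j] * w)
        oracle = oracle_raw * w[None, :]  # weighted form of the S kernel
        assert np.abs(S - oracle).max() < 1e-10 * np.abs(oracle).max()


class TestInferInput:
    def test_round_trip_known_input(self, unit_domain, rng):
        raw = random_symmetric_ec(10, 0.6, rng)
        t = transfer_from_ec(weight_ec(raw, unit_domain))
        n = rng.standard_normal(10)
        q = t.matrix @ n
        assert np.abs(infer_input(t, q) - n).max() < 1e-10

    def test_identity_transfer_passthrough(self, unit_domain, rng):
        t = TransferFunction(np.eye(10), unit_domain)
        q = rng.standard_normal(10)
        assert np.allclose(infer_input(t, q), q)

    def test_mode_space_route_agrees(self, unit_domain, rng):
        raw = random_symmetric_ec(10, 0.6, rng)
        ec = weight_ec(raw, unit_domain)
        t = transfer_from_ec(ec)
        q = rng.standard_normal(10)
        # mode-space route: N = U Theta^{-1} U^dagger Q (unit weights)
        lam, U = np.linalg.eigh(ec.weighted)
        theta = 1.0 / (1.0 - lam)
        n_modes = U @ np.diag(1.0 / theta) @ U.T @ q
        assert np.abs(infer_input(t, q) - n_modes).max() < 1e-10


class TestLowestModeRemoval:
    def test_row_integrals_vanish_and_negatives_appear(self, rng):
        # reconstruction without the uniform-sign lowest mode has
        # area-weighted zero row integrals -> negative entries
        K = 30
        dom = SpatialDomain.uniform(K, total_area=float(K))
        # build an FC dominated by a uniform-sign lowest mode
        x = np.linspace(0, 1, K, endpoint=False)
        modes = [np.ones(K)]
        for j in (1, 2):  # exact discrete-Fourier orthogonality on the grid
            modes.append(np.cos(2 * np.pi * j * x))
            modes.append(np.sin(2 * np.pi * j * x))
        modes.append(np.cos(2 * np.pi * 3 * x))
        U = np.column_stack(modes)
        U /= np.sqrt((U ** 2).sum(axis=0))[None, :]  # unit weights: plain norm
        kappa = np.array([10.0, 5.0, 3.0, 2.0, 1.0, 0.5])
        C = (U * kappa[None, :]) @ U.T
        basis, spec = eigendecompose_cov(CovarianceSpectrum(C, dom))
        # drop the lowest (largest-kappa, uniform-sign) mode
        kap = spec.kappa.copy()
        kap[0] = 0.0
        R = spectral_reconstruct(basis, kap)
        row_int = R @ dom.area_weights
        assert np.abs(row_int).max() < 1e-8
        for i in range(K):
            if np.abs(R[i]).max() > 1e-12:
                assert R[i].min() < 0

    def test_ec_from_covariance_round_trip(self, unit_domain, rng):
        raw = random_symmetric_ec(10, 0.6, rng)
        ec = weight_ec(raw, unit_domain)
        cov = covariance_from_transfer(transfer_from_ec(ec))
        back = ec_from_covariance(cov)
        assert np.abs(back.weighted - ec.weighted).max() < 1e-8
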