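"""Cross-spectral inverse solvers: sparse Bayesian learning, Hermitian
graphical models, eLORETA and LCMV baselines."""

import numpy as np
import pytest
from scipy.optimize import minimize

from meegsi import inverse as I
from meegsi.forward import SourceSpace
from meegsi.spectral import cross_spectrum, fft_coefficients
from meegsi.synth import OscillatoryNetworkSpec, project_to_sensors, simulate_oscillatory_sources


def random_hpsd(n, seed, jitter=0.5):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    return A @ A.conj().T / n + jitter * np.eye(n)


@pytest.fixture(scope="module")
def alpha_recovery(head, source_cap, sensors, leadfield_sphere):
    """Alpha-band network of 3 planted sources observed at 19 sensors."""
    active = (40, 200, 411)
    spec = OscillatoryNetworkSpec(
        n_sources=500, active=active, center_hz=10.0, bandwidth_hz=2.0,
        amplitude=1.0, noise_floor=0.02, n_time=200 * 100, sampling_rate=200.0, seed=3,
    )
    srcs, _ = simulate_oscillatory_sources(spec)
    v = project_to_sensors(leadfield_sphere, srcs, snr_db=10.0, seed=4)
    S = cross_spectrum(fft_coefficients(v, 100, window=None))
    fi = int(np.argmin(np.abs(S.frequencies - 10.0)))
    return S.S[:, :, fi], active


@pytest.fixture(scope="module")
def hermitian_graph_samples():
    """10-node sparse Hermitian precision, m = 2000 complex Gaussian draws."""
    rng = np.random.default_rng(5)
    n = 10
    Theta = np.eye(n, dtype=complex)
    edges = [(i, (i + 1) % n) for i in range(n)] + [(0, 5), (2, 7)]
    for i, j in edges:
        w = 0.35 * np.exp(1j * rng.uniform(-np.pi, np.pi))
        Theta[i, j] = w
        Theta[j, i] = np.conj(w)
    Theta += 0.1 * np.eye(n)
    Sigma = np.linalg.inv(Theta)
    A = np.linalg.cholesky(Sigma)
    m = 2000
    Z = A @ ((rng.standard_normal((n, m)) + 1j * rng.standard_normal((n, m))) / np.sqrt(2))
    Shat = Z @ Z.conj().T / m
    true_edges = {tuple(sorted(e)) for e in edges}
    return Shat, true_edges, Theta


def edge_set(Th, tol=1e-8):
    n = Th.shape[0]
    return {(i, j) for i in range(n) for j in range(i + 1, n) if abs(Th[i, j]) > tol}


def edge_f1(est, true):
    tp = len(est & true)
    return 2 * tp / max(2 * tp + len(est - true) + len(true - est), 1)


class TestSSSBL:
    def test_identity_leadfield_low_noise_recovers_input(self):
        S = random_hpsd(6, 0)
        cfg = I.SolverConfig(alpha1=0.0, alpha2=0.0, noise_variance=1e-8, max_iter=500, tolerance=1e-10)
        _, xspec, _, _ = I.sssbl_solve(S, np.eye(6), m=100, cfg=cfg)
        assert np.abs(xspec.S_jj[:, :, 0] - S).max() < 1e-5 * np.abs(S).max()

    def test_planted_alpha_sources_in_top10_neighborhoods(self, alpha_recovery, leadfield_sphere, one_ring):
        S_vv, active = alpha_recovery
        op, xspec, gam, support = I.sssbl_solve(
            S_vv, leadfield_sphere, m=200, cfg=I.SolverConfig(alpha1=1.0)
        )
        top10 = set(np.argsort(xspec.spectra[:, 0])[::-1][:10].tolist())
        for a in active:
            assert top10 & one_ring[a], f"source {a} not near any top-10 estimate"

    def test_penalty_monotonically_shrinks_prior_mass(self, alpha_recovery, leadfield_sphere):
        # the elastic-net penalty only shrinks: total prior scale mass is
        # non-increasing in alpha1 (the thresholded support of the interior
        # solution has no comparable guarantee; see the methods note)
        S_vv, _ = alpha_recovery
        masses = []
        for a1 in (1.0, 10.0, 100.0):
            _, _, gam, _ = I.sssbl_solve(
                S_vv, leadfield_sphere, m=200, cfg=I.SolverConfig(alpha1=a1)
            )
            masses.append(float(gam.sum()))
        assert masses[0] >= masses[1] >= masses[2]

    def test_zero_column_rejected(self):
        L = np.ones((4, 5))
        L[:, 2] = 0.0
        with pytest.raises(ValueError, match="zero column"):
            I.sssbl_solve(np.eye(4), L)

    def test_non_psd_input_rejected(self, leadfield_sphere):
        bad = -np.eye(19)
        with pytest.raises(ValueError, match="positive semidefinite"):
            I.sssbl_solve(bad, leadfield_sphere)


class TestSupportThresholds:
    def test_threshold_zero_includes_all(self):
        prob = np.array([[0.0, 0.5], [0.9, 0.1]])
        assert I.sssbl_support(prob, 0.0).all()

    def test_threshold_one_keeps_only_certainty(self):
        prob = np.array([[1.0], [0.999]])
        mask = I.sssbl_support(prob, 1.0)
        assert mask.tolist() == [[True], [False]]

    def test_joint_union_gives_transverse_pattern(self):
        prob = np.array([[0.99, 0.1], [0.1, 0.99], [0.1, 0.1]])
        mask = I.sssbl_support(prob, 0.5, joint="union")
        assert mask.tolist() == [[True, True], [True, True], [False, False]]


class TestHGRidge:
    def test_identity_input_closed_form_value(self):
        Th = I.hgridge_solve(np.eye(3, dtype=complex), 1.0)
        assert np.allclose(np.diag(Th).real, (np.sqrt(5) - 1) / 2, atol=1e-12)
        assert np.abs(Th - np.diag(np.diag(Th))).max() < 1e-12

    def test_alpha_to_zero_approaches_inverse(self):
        S = random_hpsd(4, 1)
        Th = I.hgridge_solve(S, 1e-8)
        assert np.abs(Th - np.linalg.inv(S)).max() < 1e-5

    def test_matches_gradient_based_optimizer(self):
        """Independent oracle: L-BFGS on the real parameterization of the
        penalized objective agrees with the eigendecomposition closed form."""
        n, alpha = 5, 0.3
        S = random_hpsd(n, 2)
        Th = I.hgridge_solve(S, alpha)
        iu, iu1 = np.triu_indices(n), np.triu_indices(n, 1)

        def unpack(v):
            T = np.zeros((n, n), complex)
            k = len(iu[0])
            T[iu] = v[:k]
            T[iu1] += 1j * v[k:]
            return T + np.triu(T, 1).conj().T

        def obj_grad(v):
            T = unpack(v)
            if np.linalg.eigvalsh(T)[0] <= 1e-10:
                return 1e8 * (1.0 - np.linalg.eigvalsh(T)[0]), np.zeros_like(v)
            G = -np.linalg.inv(T) + S + alpha * T
            k = len(iu[0])
            g = np.zeros_like(v)
            g[:k] = np.where(iu[0] == iu[1], G.real[iu], 2 * G.real[iu])
            g[k:] = 2 * G.imag[iu1]
            return I.hgridge_objective(T, S, alpha), g

        v0 = np.concatenate([(Th + 0.1 * np.eye(n))[iu].real, Th[iu1].imag])
        res = minimize(obj_grad, v0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=10000, ftol=1e-18, gtol=1e-13))
        assert np.abs(unpack(res.x) - Th).max() < 1e-6

    def test_beats_random_perturbations(self):
        S = random_hpsd(5, 3)
        alpha = 0.4
        Th = I.hgridge_solve(S, alpha)
        base = I.hgridge_objective(Th, S, alpha)
        rng = np.random.default_rng(4)
        for _ in range(100):
            Pm = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
            Pm = 0.01 * (Pm + Pm.conj().T) / 2
            assert I.hgridge_objective(Th + Pm, S, alpha) >= base - 1e-10

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            I.hgridge_solve(np.eye(2), 0.0)


class TestHGLASSO:
    def test_unpenalized_equals_inverse(self):
        S = random_hpsd(5, 1)
        assert np.abs(I.hglasso_solve(S, 0.0) - np.linalg.inv(S)).max() < 1e-6

    def test_saturating_alpha_gives_exact_diagonal(self):
        S = random_hpsd(5, 6)
        off = ~np.eye(5, dtype=bool)
        alpha = np.abs(S[off]).max() * 1.01
        Th = I.hglasso_solve(S, alpha)
        assert np.abs(Th[off]).max() == 0.0
        assert np.allclose(np.diag(Th).real, 1.0 / np.diag(S).real, atol=1e-8)

    def test_edge_pattern_recovered_at_oracle_alpha(self, hermitian_graph_samples):
        Shat, true_edges, _ = hermitian_graph_samples
        best = max(
            edge_f1(edge_set(I.hglasso_solve(Shat, a)), true_edges)
            for a in (0.05, 0.1, 0.15)
        )
        assert best >= 0.8

    def test_edges_monotone_in_alpha(self, hermitian_graph_samples):
        Shat, _, _ = hermitian_graph_samples
        sizes = [len(edge_set(I.hglasso_solve(Shat, a))) for a in (0.02, 0.1, 0.3)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_objective_not_worse_than_ridge_solution(self):
        S = random_hpsd(4, 7)
        alpha = 0.2
        Th = I.hglasso_solve(S, alpha)
        ref = I.hgridge_solve(S, alpha)
        assert I.hglasso_objective(Th, S, alpha) <= I.hglasso_objective(ref, S, alpha) + 1e-8


class TestHIGGS:
    def test_two_step_singleton_support_is_reciprocal(self):
        S = np.diag([4.0, 9.0]).astype(complex)
        pt = I.higgs_two_step(S[:, :, None], support=np.array([True, False]))
        assert pt.theta[0, 0, 0].real == pytest.approx(0.25, rel=1e-6)
        assert pt.theta[1, 1, 0] == 0.0

    def test_two_step_identity_spectrum_gives_diagonal(self):
        S = np.eye(5, dtype=complex)
        pt = I.higgs_two_step(S[:, :, None], cfg=I.SolverConfig(type2="hglasso", alpha_graph=0.1))
        off = ~np.eye(5, dtype=bool)
        assert np.abs(pt.theta[:, :, 0][off]).max() < 1e-8

    def test_two_step_recovers_connectivity_edges(self, hermitian_graph_samples):
        Shat, true_edges, _ = hermitian_graph_samples
        pt = I.higgs_two_step(
            Shat[:, :, None], cfg=I.SolverConfig(type2="hglasso", alpha_graph=0.1)
        )
        assert edge_f1(edge_set(pt.theta[:, :, 0]), true_edges) >= 0.6

    def test_one_step_identity_model_reduces_to_graphical_solver(self, hermitian_graph_samples):
        Shat, _, _ = hermitian_graph_samples
        cfg = I.SolverConfig(type2="hglasso", alpha_graph=0.1, noise_variance=1e-12,
                             max_iter=50, tolerance=1e-9)
        pt, _ = I.higgs_one_step(Shat + 1e-12 * np.eye(10), np.eye(10), cfg=cfg)
        direct = I.hglasso_solve(Shat, 0.1)
        assert np.abs(pt.theta[:, :, 0] - direct).max() < 1e-5

    def test_one_step_agrees_with_two_step_on_low_noise(self, hermitian_graph_samples):
        Shat, true_edges, _ = hermitian_graph_samples
        rng = np.random.default_rng(8)
        L = np.eye(10) + 0.1 * rng.standard_normal((10, 10))
        sigma2 = 1e-4
        Svv = L @ Shat @ L.T + sigma2 * np.eye(10)
        cfg = I.SolverConfig(type2="hglasso", alpha_graph=0.1, noise_variance=sigma2,
                             max_iter=100, tolerance=1e-7)
        pt1, op = I.higgs_one_step(Svv, L, cfg=cfg)
        pt2 = I.higgs_two_step(Shat[:, :, None], cfg=cfg)
        e1, e2 = edge_set(pt1.theta[:, :, 0]), edge_set(pt2.theta[:, :, 0])
        assert len(e1 & e2) / max(len(e1 | e2), 1) >= 0.7

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            I.higgs_two_step(np.eye(3, dtype=complex)[:, :, None], support=np.zeros(3, bool))


class TestELORETA:
    def test_exact_localization_of_noiseless_point_sources(self, leadfield_sphere):
        op = I.eloreta_solve(None, leadfield_sphere, reg=1e-8)
        T = op.T[:, :, 0]
        # power map column j = response to a unit dipole at source j
        P = np.abs(T @ leadfield_sphere.matrix) ** 2
        loc = np.argmax(P, axis=0)
        assert np.array_equal(loc, np.arange(leadfield_sphere.n_sources))

    def test_weight_fixed_point_converged(self, leadfield_sphere):
        op = I.eloreta_solve(None, leadfield_sphere, reg=1e-8, tol=1e-8)
        w = op.weights
        Lm = leadfield_sphere.matrix
        K0 = (Lm / w[None, :]) @ Lm.T
        K = K0 + 1e-8 * np.trace(K0) / Lm.shape[0] * np.eye(Lm.shape[0])
        Minv = np.linalg.pinv(K, hermitian=True)
        w_next = np.sqrt(np.einsum("ni,nm,mi->i", Lm, Minv, Lm))
        assert np.abs(w_next - w).max() / w.max() < 1e-6

    def test_power_scales_quadratically_with_data(self, leadfield_sphere):
        op = I.eloreta_solve(None, leadfield_sphere, reg=1e-8)
        rng = np.random.default_rng(9)
        C = random_hpsd(19, 10)
        from meegsi.spectral import CrossSpectralTensor

        t1 = I.apply_operator(op, CrossSpectralTensor(C[:, :, None], np.array([0.0]), 10))
        t2 = I.apply_operator(op, CrossSpectralTensor(9 * C[:, :, None], np.array([0.0]), 10))
        assert np.allclose(t2.spectra, 9 * t1.spectra)


class TestLCMV:
    def test_unit_gain_constraint(self, leadfield_sphere):
        C = random_hpsd(19, 11, jitter=1.0)
        op = I.lcmv_solve(C, leadfield_sphere, reg=0.0)
        gains = np.einsum("sn,ns->s", op.T[:, :, 0], leadfield_sphere.matrix.astype(complex))
        assert np.abs(gains - 1).max() < 1e-10

    def test_white_covariance_gives_matched_filter(self):
        rng = np.random.default_rng(12)
        L = rng.standard_normal((8, 20))
        op = I.lcmv_solve(np.eye(8), L, reg=0.0)
        expected = (L / (L**2).sum(axis=0)[None, :]).T
        assert np.allclose(op.T[:, :, 0].real, expected, atol=1e-10)

    def test_interference_suppression(self, leadfield_sphere):
        # two uncorrelated sources: the filter for source A responds to
        # source B at least 20 dB below its unit gain
        Lm = leadfield_sphere.matrix
        a, b = 100, 400
        C = np.outer(Lm[:, a], Lm[:, a]) + np.outer(Lm[:, b], Lm[:, b])
        C = C + 1e-6 * np.trace(C) / 19 * np.eye(19)
        op = I.lcmv_solve(C, leadfield_sphere, reg=0.0)
        leak = abs(op.T[a, :, 0] @ Lm[:, b]) * np.linalg.norm(Lm[:, b]) / np.linalg.norm(Lm[:, a])
        assert 20 * np.log10(max(abs(op.T[a, :, 0] @ Lm[:, a]), 1e-300) / max(abs(op.T[a, :, 0] @ Lm[:, b]), 1e-300)) >= 20


class TestApplyOperator:
    def test_identity_operator_preserves_metric(self):
        from meegsi.spectral import CrossSpectralTensor

        op = I.QuasilinearOperator(np.eye(4, dtype=complex)[:, :, None], np.array([0.0]))
        C = random_hpsd(4, 13)
        out = I.apply_operator(op, CrossSpectralTensor(C[:, :, None], np.array([0.0]), 5))
        assert np.allclose(out.S_jj[:, :, 0], C)

    def test_hermitian_psd_preserved(self):
        rng = np.random.default_rng(14)
        T = rng.standard_normal((6, 4)) + 1j * rng.standard_normal((6, 4))
        op = I.QuasilinearOperator(T[:, :, None], np.array([0.0]))
        C = random_hpsd(4, 15)
        from meegsi.spectral import CrossSpectralTensor

        out = I.apply_operator(op, CrossSpectralTensor(C[:, :, None], np.array([0.0]), 5)).S_jj[:, :, 0]
        assert np.abs(out - out.conj().T).max() < 1e-10
        assert np.linalg.eigvalsh(out).min() > -1e-10 * np.abs(out).max()

    def test_compression_consistency_with_solver_output(self, alpha_recovery, leadfield_sphere):
        # applying the stored operator to the data tensor reproduces the
        # operator part of the solver's source cross-spectrum
        S_vv, _ = alpha_recovery
        cfg = I.SolverConfig(alpha1=1.0)
        op, xspec, gam, _ = I.sssbl_solve(S_vv, leadfield_sphere, m=200, cfg=cfg)
        T = op.T[:, :, 0]
        direct = T @ S_vv @ T.conj().T
        Lm = leadfield_sphere.matrix
        post = np.diag(gam[:, 0]) - (T @ Lm) * gam[None, :, 0]
        assert np.abs(direct + post - xspec.S_jj[:, :, 0]).max() < 1e-10 * max(np.abs(xspec.S_jj).max(), 1e-300)

    def test_axis_mismatch_rejected(self):
        op = I.QuasilinearOperator(np.zeros((3, 4, 2), dtype=complex), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="frequency axes"):
            I.apply_operator(op, np.zeros((4, 5, 7), dtype=complex))
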