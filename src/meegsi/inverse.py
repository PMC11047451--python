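"""Cross-spectral inverse solvers.

Two regularization families act on the per-frequency Hermitian cross-spectral
matrices of the data:

* **type one** (spectra / activation): structured sparse Bayesian learning
  over per-source variance scales gamma under the complex Gaussian model
  v ~ CN(0, L diag(gamma) L^H + sigma^2 I), with an elastic-net-style penalty
  alpha1 * sum sqrt(gamma) + alpha2 * sum gamma combining a square-root
  quasinorm with a linear (nuclear, on the diagonal model) term.  The output
  is a per-frequency quasilinear inverse operator T = G L^H (L G L^H +
  sigma^2 I)^-1, the posterior source cross-spectrum, and a sparse support.
* **type two** (cross-spectra / connectivity): Hermitian graphical models for
  the source precision matrix -- HGRidge (Frobenius penalty, closed form via
  eigendecomposition) and HGLASSO (modulus l1 on off-diagonal entries, ADMM)
  -- either two-step on an SSSBL source cross-spectrum or one-step by
  EM on the sensor cross-spectrum.

eLORETA (weight fixed point, exact localization of noise-free point sources)
and the LCMV beamformer (unit-gain minimum-variance rows) are included as
baselines.  All solvers accept a single Hermitian slice or a full tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .spectral import CrossSpectralTensor


@dataclass
class SolverConfig:
    method: str = "sssbl"
    type2: str = "hglasso"
    alpha1: float = 1.0
    alpha2: float = 0.0
    alpha_graph: float = 0.1
    noise_variance: float | None = None
    max_iter: int = 500
    tolerance: float = 1e-6
    support_threshold: float = 0.95


@dataclass
class QuasilinearOperator:
    """Per-frequency source-from-sensor operator (S x N complex slices)."""

    T: np.ndarray  # (S, N, F)
    frequencies: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class SourceCrossSpectrum:
    S_jj: np.ndarray  # (S, S, F) complex Hermitian PSD
    frequencies: np.ndarray

    @property
    def spectra(self) -> np.ndarray:
        """Real nonnegative diagonal slices (S x F)."""
        return np.real(np.einsum("iif->if", self.S_jj))


@dataclass
class PrecisionTensor:
    theta: np.ndarray  # (S, S, F) Hermitian PD
    support: np.ndarray  # (S, S, F) boolean, symmetric, true diagonal
    frequencies: np.ndarray


def estimate_noise_variance(S_vv: np.ndarray) -> float:
    """Default sensor noise variance: mean of the smallest ceil(N/4)
    eigenvalues of the cross-spectral slice."""
    ev = np.linalg.eigvalsh(0.5 * (S_vv + S_vv.conj().T))
    k = int(np.ceil(S_vv.shape[0] / 4))
    return float(max(np.mean(ev[:k].real), 1e-12 * max(ev[-1].real, 1e-300)))


def _as_slices(S):
    """Normalize a slice / tensor input to (list_of_slices, freqs)."""
    if isinstance(S, CrossSpectralTensor):
        return [S.S[:, :, i] for i in range(S.S.shape[2])], np.asarray(S.frequencies), S.m
    S = np.asarray(S)
    if S.ndim == 2:
        return [S], np.array([0.0]), 1
    return [S[:, :, i] for i in range(S.shape[2])], np.arange(S.shape[2], dtype=float), 1


def _check_hermitian_psd(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M)
    scale = max(np.linalg.norm(M), 1e-300)
    if np.linalg.norm(M - M.conj().T) > 1e-8 * scale:
        raise ValueError(f"{name} is not Hermitian")
    M = 0.5 * (M + M.conj().T)
    ev_min = np.linalg.eigvalsh(M)[0].real
    if ev_min < -1e-8 * scale:
        raise ValueError(f"{name} is not positive semidefinite")
    return M


# ---------------------------------------------------------------------------
# SSSBL (type-one)


def _penalized_gamma_update(q: np.ndarray, m_eff: np.ndarray, alpha1: float, alpha2: float) -> np.ndarray:
    """Per-coordinate scale update: minimize m_eff*(log g + q/g) +
    alpha1*sqrt(g) + alpha2*g over g > 0.

    ``m_eff`` may be a vector (per-coordinate effective sample count, e.g.
    m * diag(T L) under the MacKay linearization).  Newton iteration on
    u = sqrt(g); the unpenalized solution is g = q.
    """
    q = np.asarray(q, dtype=np.float64)
    # floor tiny (pruned) scales well above underflow so u**4 stays finite
    q = np.maximum(q, 1e-18 * max(np.max(q), 1e-280))
    m_eff = np.maximum(np.asarray(m_eff, dtype=np.float64), 1e-12)
    if alpha1 == 0 and alpha2 == 0:
        return q
    u = np.sqrt(q)
    for _ in range(60):
        # d/du of m_eff*(2*log u + q/u^2) + alpha1*u + alpha2*u^2
        f1 = 2 * m_eff / u - 2 * m_eff * q / u**3 + alpha1 + 2 * alpha2 * u
        f2 = -2 * m_eff / u**2 + 6 * m_eff * q / u**4 + 2 * alpha2
        step = f1 / np.maximum(f2, 1e-300)
        u_new = np.clip(u - step, 0.1 * u, 10 * u)
        if np.max(np.abs(u_new - u) / np.maximum(u, 1e-30)) < 1e-12:
            u = u_new
            break
        u = u_new
    return u**2


def sssbl_solve(
    S_vv,
    L: LeadField | np.ndarray,
    m: int | None = None,
    cfg: SolverConfig | None = None,
    groups: dict | None = None,
):
    """Spectral structured sparse Bayesian learning, per frequency slice.

    Evidence maximization over per-source variance scales gamma with the
    elastic-net penalty alpha1*sum(sqrt(gamma)) + alpha2*sum(gamma); under a
    ``groups`` mapping the scale is shared within each group.  Returns
    ``(QuasilinearOperator, SourceCrossSpectrum, gammas, support)``.
    """
    cfg = cfg or SolverConfig()
    slices, freqs, m_t = _as_slices(S_vv)
    m = m_t if m is None else m
    Lm = L.matrix if isinstance(L, LeadField) else np.asarray(L)
    if not np.all(np.isfinite(Lm)):
        raise ValueError("lead field contains non-finite entries")
    if np.any(np.linalg.norm(Lm, axis=0) == 0):
        raise ValueError("lead field has an all-zero column")
    N, S = Lm.shape
    F = len(slices)
    T_all = np.zeros((S, N, F), dtype=complex)
    Sjj_all = np.zeros((S, S, F), dtype=complex)
    gam_all = np.zeros((S, F))
    prob_all = np.zeros((S, F))
    for fi, Sv in enumerate(slices):
        Sv = _check_hermitian_psd(Sv, "data cross-spectrum")
        sigma2 = cfg.noise_variance
        if sigma2 is None:
            sigma2 = estimate_noise_variance(Sv)
        scale = np.real(np.trace(Sv)) / max(np.real(np.trace(Lm @ Lm.T)), 1e-300)
        gam = np.full(S, max(scale, 1e-12))
        for _ in range(cfg.max_iter):
            G = gam[None, :] * Lm  # L * diag(gam)
            Sigma_v = G @ Lm.T + sigma2 * np.eye(N)
            Minv = np.linalg.inv(Sigma_v)
            T = G.T.conj() @ Minv  # (S, N) = diag(gam) L^H Sigma^-1
            TL = T @ Lm  # (S, S)
            # MacKay fixed point: posterior mean power p over the learning
            # fraction lam = diag(T L), with the elastic-net penalty folded
            # into the per-coordinate scalar problem
            p = np.maximum(np.real(np.einsum("in,nm,im->i", T, Sv, T.conj())), 0.0)
            lam = np.clip(np.real(np.diag(TL)), 1e-12, 1.0)
            q = p / lam
            m_eff = m * lam
            if groups:
                for idx in groups.values():
                    q[idx] = q[idx].mean()
                    m_eff[idx] = m_eff[idx].mean()
            gam_new = _penalized_gamma_update(q, m_eff, cfg.alpha1, cfg.alpha2)
            if groups:
                for idx in groups.values():
                    gam_new[idx] = gam_new[idx].mean()
            delta = np.max(np.abs(gam_new - gam) / np.maximum(gam, 1e-30))
            gam = gam_new
            if delta < cfg.tolerance:
                break
        G = gam[None, :] * Lm
        Sigma_v = G @ Lm.T + sigma2 * np.eye(N)
        Minv = np.linalg.inv(Sigma_v)
        T = G.T.conj() @ Minv
        TL = T @ Lm
        post_cov = np.diag(gam) - TL * gam[None, :]  # Gamma - T L Gamma
        Sjj = T @ Sv @ T.conj().T + post_cov
        Sjj = 0.5 * (Sjj + Sjj.conj().T)
        T_all[:, :, fi] = T
        Sjj_all[:, :, fi] = Sjj
        gam_all[:, fi] = gam
        # posterior concentration: fraction of the prior scale explained by
        # the data (diag of T L), in [0, 1]
        prob_all[:, fi] = np.clip(np.real(np.diag(TL)), 0.0, 1.0)
    op = QuasilinearOperator(
        T_all, freqs, provenance={"method": "sssbl", "alpha1": cfg.alpha1, "alpha2": cfg.alpha2}
    )
    xspec = SourceCrossSpectrum(Sjj_all, freqs)
    support = sssbl_support(prob_all, cfg.support_threshold)
    op.posterior_probability = prob_all  # type: ignore[attr-defined]
    return op, xspec, gam_all, support


def sssbl_support(prob: np.ndarray, threshold: float, joint: str | None = None) -> np.ndarray:
    """Threshold the posterior concentration into a boolean support mask.

    ``joint='union'``/``'intersection'`` combines across the frequency axis
    into a single transverse pattern repeated at each frequency.
    """
    mask = prob >= threshold if threshold > 0 else np.ones_like(prob, dtype=bool)
    if threshold >= 1:
        mask = prob >= 1.0
    if joint == "union":
        m = mask.any(axis=1)
        mask = np.repeat(m[:, None], mask.shape[1], axis=1)
    elif joint == "intersection":
        m = mask.all(axis=1)
        mask = np.repeat(m[:, None], mask.shape[1], axis=1)
    return mask


# ---------------------------------------------------------------------------
# HGRidge / HGLASSO (type-two)


def hgridge_solve(S, alpha: float) -> np.ndarray:
    """Hermitian graphical ridge: closed-form PD stationary point of
    -logdet(Theta) + tr(S Theta) + (alpha/2) ||Theta||_F^2.

    Shares eigenvectors with S; eigenvalues theta_i = (-d_i +
    sqrt(d_i^2 + 4 alpha)) / (2 alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    S = _check_hermitian_psd(S, "cross-spectrum")
    d, U = np.linalg.eigh(S)
    theta = (-d + np.sqrt(d**2 + 4.0 * alpha)) / (2.0 * alpha)
    return (U * theta[None, :]) @ U.conj().T


def hglasso_solve(
    S,
    alpha_graph: float,
    rho: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Hermitian graphical lasso via ADMM.

    Minimizes -logdet(Theta) + tr(S Theta) + alpha_graph * sum_{i!=j}
    |Theta_ij| over Hermitian PD matrices; the l1 acts on complex moduli
    (phase-rotation invariant) and the diagonal is unpenalized.
    """
    S = np.asarray(S, dtype=complex)
    S = 0.5 * (S + S.conj().T)
    if np.any(np.real(np.diag(S)) <= 0):
        raise ValueError("cross-spectrum diagonal must be positive")
    n = S.shape[0]
    if alpha_graph == 0:
        return np.linalg.inv(S)
    Z = np.linalg.inv(S + alpha_graph * np.eye(n))
    U = np.zeros_like(Z)
    off = ~np.eye(n, dtype=bool)
    Theta = Z.copy()
    for it in range(max_iter):
        # Theta update: argmin -logdet + tr(S Theta) + rho/2 ||Theta - Z + U||^2
        A = rho * (Z - U) - S
        A = 0.5 * (A + A.conj().T)
        d, Q = np.linalg.eigh(A)
        theta_ev = (d + np.sqrt(d**2 + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_ev[None, :]) @ Q.conj().T
        # Z update: modulus soft threshold off-diagonal
        W = Theta + U
        Z_new = W.copy()
        mod = np.abs(W)
        shrink = np.maximum(1.0 - (alpha_graph / rho) / np.maximum(mod, 1e-300), 0.0)
        Z_new[off] = (W * shrink)[off]
        r_primal = np.linalg.norm(Theta - Z_new)
        r_dual = rho * np.linalg.norm(Z_new - Z)
        Z = Z_new
        U = U + Theta - Z
        if max(r_primal, r_dual) < tol * max(1.0, np.linalg.norm(Z)):
            break
    else:
        raise RuntimeError(
            f"hglasso did not converge: primal residual {r_primal:.2e} after {max_iter} iterations"
        )
    out = 0.5 * (Z + Z.conj().T)
    # keep exact PD by returning the Theta iterate's symmetrization with the
    # sparsity pattern of Z
    pat = np.abs(Z) > 0
    Theta = 0.5 * (Theta + Theta.conj().T)
    Theta[~pat & off] = 0.0
    return 0.5 * (Theta + Theta.conj().T)


def hglasso_objective(Theta: np.ndarray, S: np.ndarray, alpha_graph: float) -> float:
    off = ~np.eye(S.shape[0], dtype=bool)
    sign, logdet = np.linalg.slogdet(Theta)
    if sign.real <= 0:
        return np.inf
    return float(
        -logdet + np.real(np.trace(S @ Theta)) + alpha_graph * np.sum(np.abs(Theta[off]))
    )


def hgridge_objective(Theta: np.ndarray, S: np.ndarray, alpha: float) -> float:
    sign, logdet = np.linalg.slogdet(Theta)
    if sign.real <= 0:
        return np.inf
    return float(
        -logdet + np.real(np.trace(S @ Theta)) + 0.5 * alpha * np.linalg.norm(Theta) ** 2
    )


# ---------------------------------------------------------------------------
# HIGGS


def _support_mask(support, S: int) -> np.ndarray:
    support = np.asarray(support)
    if support.dtype == bool:
        idx = np.flatnonzero(support)
    else:
        idx = support.astype(np.int64)
    if idx.size == 0:
        raise ValueError("empty source support")
    return idx


def higgs_two_step(
    S_jj: SourceCrossSpectrum | np.ndarray,
    cfg: SolverConfig | None = None,
    support=None,
) -> PrecisionTensor:
    """Two-step graphical estimate: HGLASSO/HGRidge on the (support-restricted)
    source cross-spectrum from a type-one solve; off-support entries are 0."""
    cfg = cfg or SolverConfig()
    if isinstance(S_jj, SourceCrossSpectrum):
        tensor, freqs = S_jj.S_jj, S_jj.frequencies
    else:
        tensor = np.asarray(S_jj)
        if tensor.ndim == 2:
            tensor = tensor[:, :, None]
        freqs = np.arange(tensor.shape[2], dtype=float)
    S = tensor.shape[0]
    F = tensor.shape[2]
    theta_out = np.zeros((S, S, F), dtype=complex)
    supp_out = np.zeros((S, S, F), dtype=bool)
    for fi in range(F):
        if support is None:
            idx = np.arange(S)
        else:
            sup_f = support[:, fi] if np.ndim(support) == 2 else support
            idx = _support_mask(sup_f, S)
        Ssub = tensor[np.ix_(idx, idx)][:, :, fi]
        Ssub = 0.5 * (Ssub + Ssub.conj().T)
        # regularize a singular restricted spectrum minimally
        evmax = max(np.linalg.eigvalsh(Ssub)[-1].real, 1e-300)
        Ssub = Ssub + 1e-10 * evmax * np.eye(len(idx))
        if len(idx) == 1:
            Th = np.array([[1.0 / Ssub[0, 0]]])
        elif cfg.type2 == "hgridge":
            Th = hgridge_solve(Ssub, cfg.alpha_graph)
        else:
            Th = hglasso_solve(Ssub, cfg.alpha_graph)
        theta_out[np.ix_(idx, idx, [fi])] = Th[:, :, None]
        supp_out[idx[:, None], idx[None, :], fi] = np.abs(Th) > 0
        supp_out[idx, idx, fi] = True
    return PrecisionTensor(theta_out, supp_out, freqs)


def higgs_one_step(
    S_vv,
    L: LeadField | np.ndarray,
    support=None,
    cfg: SolverConfig | None = None,
):
    """One-step EM: estimate the source precision directly from the sensor
    cross-spectrum.

    E-step: posterior source cross-spectrum under v ~ CN(0, L Theta^-1 L^H +
    sigma^2 I); M-step: HGLASSO/HGRidge on it.  Raises if the penalized
    objective increases for five consecutive iterations.

    Returns ``(PrecisionTensor, QuasilinearOperator)``.
    """
    cfg = cfg or SolverConfig()
    slices, freqs, _ = _as_slices(S_vv)
    Lm = L.matrix if isinstance(L, LeadField) else np.asarray(L)
    N, S = Lm.shape
    F = len(slices)
    theta_out = np.zeros((S, S, F), dtype=complex)
    supp_out = np.zeros((S, S, F), dtype=bool)
    T_out = np.zeros((S, N, F), dtype=complex)
    for fi, Sv in enumerate(slices):
        Sv = _check_hermitian_psd(Sv, "data cross-spectrum")
        idx = np.arange(S) if support is None else _support_mask(
            support[:, fi] if np.ndim(support) == 2 else support, S
        )
        Ls = Lm[:, idx]
        k = len(idx)
        sigma2 = cfg.noise_variance
        if sigma2 is None:
            sigma2 = estimate_noise_variance(Sv)
        scale = np.real(np.trace(Sv)) / max(np.real(np.trace(Ls @ Ls.T)), 1e-300)
        Theta = np.eye(k, dtype=complex) / max(scale, 1e-12)
        prev_obj = np.inf
        bad = 0
        for it in range(cfg.max_iter):
            Sig_j = np.linalg.inv(Theta)
            Sig_j = 0.5 * (Sig_j + Sig_j.conj().T)
            Sigma_v = Ls @ Sig_j @ Ls.conj().T + sigma2 * np.eye(N)
            Minv = np.linalg.inv(Sigma_v)
            T = Sig_j @ Ls.conj().T @ Minv  # (k, N)
            Spost = T @ Sv @ T.conj().T + Sig_j - T @ Ls @ Sig_j
            Spost = 0.5 * (Spost + Spost.conj().T)
            evmax = max(np.linalg.eigvalsh(Spost)[-1].real, 1e-300)
            Spost = Spost + 1e-10 * evmax * np.eye(k)
            if k == 1:
                Theta_new = np.array([[1.0 / Spost[0, 0]]])
            elif cfg.type2 == "hgridge":
                Theta_new = hgridge_solve(Spost, cfg.alpha_graph)
            else:
                Theta_new = hglasso_solve(Spost, cfg.alpha_graph)
            obj = _higgs_objective(Theta_new, Sv, Ls, sigma2, cfg)
            if obj > prev_obj + 1e-9 * max(abs(prev_obj), 1.0):
                bad += 1
                if bad >= 5:
                    raise RuntimeError(
                        f"one-step EM diverging at iteration {it}: objective {obj:.6g} "
                        f"after {prev_obj:.6g}"
                    )
            else:
                bad = 0
            delta = np.linalg.norm(Theta_new - Theta) / max(np.linalg.norm(Theta), 1e-300)
            Theta = Theta_new
            prev_obj = min(prev_obj, obj)
            if delta < cfg.tolerance:
                break
        Sig_j = np.linalg.inv(Theta)
        Sigma_v = Ls @ Sig_j @ Ls.conj().T + sigma2 * np.eye(N)
        T = Sig_j @ Ls.conj().T @ np.linalg.inv(Sigma_v)
        theta_out[np.ix_(idx, idx, [fi])] = Theta[:, :, None]
        supp_out[idx[:, None], idx[None, :], fi] = np.abs(Theta) > 0
        supp_out[idx, idx, fi] = True
        T_out[idx[:, None], np.arange(N)[None, :], fi] = T
    op = QuasilinearOperator(T_out, freqs, provenance={"method": f"higgs_one_step_{cfg.type2}"})
    return PrecisionTensor(theta_out, supp_out, freqs), op


def _higgs_objective(Theta, Sv, Ls, sigma2, cfg: SolverConfig) -> float:
    """Penalized negative marginal log-likelihood of the one-step model."""
    k = Theta.shape[0]
    Sig_j = np.linalg.inv(Theta)
    Sigma_v = Ls @ Sig_j @ Ls.conj().T + sigma2 * np.eye(Ls.shape[0])
    sign, logdet = np.linalg.slogdet(Sigma_v)
    nll = float(logdet.real + np.real(np.trace(np.linalg.solve(Sigma_v, Sv))))
    off = ~np.eye(k, dtype=bool)
    if cfg.type2 == "hgridge":
        pen = 0.5 * cfg.alpha_graph * float(np.linalg.norm(Theta) ** 2)
    else:
        pen = cfg.alpha_graph * float(np.sum(np.abs(Theta[off])))
    return nll + pen


# ---------------------------------------------------------------------------
# baselines


def eloreta_solve(
    C_vv,
    L: LeadField | np.ndarray,
    reg: float = 1e-8,
    max_iter: int = 500,
    tol: float = 1e-8,
):
    """eLORETA weight fixed point for a constrained lead field.

    Iterates w_i = sqrt(l_i^T (L W^-1 L^T + reg*I)^+ l_i) to convergence,
    then T = W^-1 L^T (L W^-1 L^T + reg*I)^+.  Raises if the fixed point is
    not reached.
    """
    Lm = L.matrix if isinstance(L, LeadField) else np.asarray(L)
    N, S = Lm.shape
    w = np.ones(S)
    converged = False

    def _K(w):
        K0 = (Lm / w[None, :]) @ Lm.T
        # regularization relative to the covariance scale (scale-free)
        return K0 + reg * np.trace(K0) / N * np.eye(N)

    for _ in range(max_iter):
        Minv = np.linalg.pinv(_K(w), hermitian=True)
        w_new = np.sqrt(np.maximum(np.einsum("ni,nm,mi->i", Lm, Minv, Lm), 1e-300))
        delta = np.max(np.abs(w_new - w) / np.maximum(w, 1e-300))
        w = w_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"eLORETA weights did not converge (last change {delta:.2e})")
    T = (Lm / w[None, :]).T @ np.linalg.pinv(_K(w), hermitian=True)
    op = QuasilinearOperator(T[:, :, None], np.array([0.0]), provenance={"method": "eloreta"})
    op.weights = w  # type: ignore[attr-defined]
    return op


def lcmv_solve(C_vv, L: LeadField | np.ndarray, reg: float = 1e-8):
    """LCMV beamformer: row i = l_i^H C^-1 / (l_i^H C^-1 l_i) (unit gain)."""
    Lm = L.matrix if isinstance(L, LeadField) else np.asarray(L)
    slices, freqs, _ = _as_slices(C_vv)
    N, S = Lm.shape
    T = np.zeros((S, N, len(slices)), dtype=complex)
    for fi, C in enumerate(slices):
        C = 0.5 * (C + C.conj().T)
        Creg = C + reg * np.trace(C).real / N * np.eye(N) if reg > 0 else C
        try:
            Cinv = np.linalg.inv(Creg)
        except np.linalg.LinAlgError as exc:
            raise ValueError("regularized covariance is singular") from exc
        num = Cinv @ Lm  # (N, S)
        den = np.real(np.einsum("ni,ni->i", Lm.conj(), num))
        T[:, :, fi] = (num / den[None, :]).conj().T
    return QuasilinearOperator(T, freqs, provenance={"method": "lcmv", "reg": reg})


def apply_operator(T: QuasilinearOperator, X):
    """Apply a quasilinear operator to a data metric.

    Coefficients (N x F x m) map to T_f z; cross-spectral tensors map to
    T_f S_f T_f^H (Hermitian PSD preserved).
    """
    if isinstance(X, CrossSpectralTensor):
        F = X.S.shape[2]
        if T.T.shape[2] not in (F, 1):
            raise ValueError("frequency axes do not match")
        out = np.empty((T.T.shape[0], T.T.shape[0], F), dtype=complex)
        for fi in range(F):
            Tf = T.T[:, :, min(fi, T.T.shape[2] - 1)]
            M = Tf @ X.S[:, :, fi] @ Tf.conj().T
            out[:, :, fi] = 0.5 * (M + M.conj().T)
        return SourceCrossSpectrum(out, np.asarray(X.frequencies))
    X = np.asarray(X)
    if X.ndim == 3:  # coefficients (N, F, m)
        F = X.shape[1]
        if T.T.shape[2] not in (F, 1):
            raise ValueError("frequency axes do not match")
        out = np.empty((T.T.shape[0], F, X.shape[2]), dtype=complex)
        for fi in range(F):
            Tf = T.T[:, :, min(fi, T.T.shape[2] - 1)]
            out[:, fi, :] = Tf @ X[:, fi, :]
        return out
    if X.ndim == 2:
        if X.shape[0] == X.shape[1] and np.iscomplexobj(X):
            Tf = T.T[:, :, 0]
            M = Tf @ X @ Tf.conj().T
            return 0.5 * (M + M.conj().T)
        return T.T[:, :, 0] @ X
    raise ValueError("unsupported data metric")
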