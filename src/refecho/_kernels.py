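"""Batched kernels for echo-amplitude traces.

Echo amplitudes of a cluster with manifold Hamiltonians (H_a, H_b) are
evaluated from the eigendecompositions H_x = V_x diag(l_x) V_x^dagger and
the overlap matrix S = V_a^dagger V_b, so that propagators reduce to phase
factors and every delay-grid point is exact (no time stepping).

Hahn echo (pi/2 - tau - pi - tau):
    V(tau) = d^-1 Re Tr[U_b U_a U_b^† U_a^†]         (all at time tau)
           = d^-1 Re sum_ik e^{-i(lb_i-lb_k)tau} |P_ik(tau)|^2,
    P(tau) = S^† E_a(tau) S,  E_x(t) = diag(e^{-i l_x t}).

Refocused echo (pi/2 - tau1 - pi - (tau1+tau2) - pi - tau2):
    V = d^-1 Re Tr[W_A W_B^†],
    W_A = U_a(tau2) U_b(tau1+tau2) U_a(tau1),
    W_B = U_b(tau2) U_a(tau1+tau2) U_b(tau1),
which separates into tau1- and tau2-dependent factors contracted by a
single batched matrix product over the flattened (j, m) eigenpair index.

All functions accept a leading batch axis: H's of shape (M, d, d) give
amplitudes of shape (M, G) or (M, G1, G2).
"""
from __future__ import annotations

import numpy as np

__all__ = ["eig_pair", "hahn_amplitudes", "refocused_amplitudes"]


def eig_pair(H_alpha: np.ndarray, H_beta: np.ndarray):
    """Eigendecompose both manifold Hamiltonians; return (la, lb, S)."""
    la, Va = np.linalg.eigh(H_alpha)
    lb, Vb = np.linalg.eigh(H_beta)
    S = np.swapaxes(Va.conj(), -1, -2) @ Vb
    return la, lb, S


def hahn_amplitudes(la, lb, S, tau: np.ndarray) -> np.ndarray:
    """Hahn-echo amplitudes on a tau grid; output (..., G), real."""
    la, lb, S = np.asarray(la), np.asarray(lb), np.asarray(S)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    d = S.shape[-1]
    Sh = np.swapaxes(S.conj(), -1, -2)
    # P(tau) = S^† E_a(tau) S  -> (..., G, d, d)
    ph_a = np.exp(-1j * la[..., None, :] * tau[:, None])
    P = Sh[..., None, :, :] @ (ph_a[..., :, None] * S[..., None, :, :])
    W = P.real**2 + P.imag**2
    dlb = lb[..., :, None] - lb[..., None, :]
    cosph = np.cos(dlb[..., None, :, :] * tau[:, None, None])
    return np.einsum("...gik,...gik->...g", W, cosph) / d


def refocused_amplitudes(la, lb, S, tau1: np.ndarray, tau2: np.ndarray) -> np.ndarray:
    """Refocused-echo amplitudes on the (tau1, tau2) grid; output (..., G1, G2)."""
    la, lb, S = np.asarray(la), np.asarray(lb), np.asarray(S)
    tau1 = np.atleast_1d(np.asarray(tau1, dtype=float))
    tau2 = np.atleast_1d(np.asarray(tau2, dtype=float))
    d = S.shape[-1]
    Sh = np.swapaxes(S.conj(), -1, -2)

    def _phases(lam, t, sign):
        return np.exp(sign * 1j * lam[..., None, :] * t[:, None])  # (..., G, d)

    # X(t1) = S^† E_a(t1) S E_b(t1)^† S^†, scaled to
    # X'_{jm} = X_{jm} e^{-i lb_j t1} e^{+i la_m t1}
    ea1 = _phases(la, tau1, -1)
    X = Sh[..., None, :, :] @ (ea1[..., :, None] * S[..., None, :, :])
    X = (X * _phases(lb, tau1, +1)[..., None, :]) @ Sh[..., None, :, :]
    X = X * _phases(lb, tau1, -1)[..., :, None] * _phases(la, tau1, +1)[..., None, :]

    # Y(t2) = S E_b(t2)^† S^† E_a(t2) S, scaled to
    # Y'_{mj} = Y_{mj} e^{+i la_m t2} e^{-i lb_j t2}
    eb2c = _phases(lb, tau2, +1)
    Y = S[..., None, :, :] @ (eb2c[..., :, None] * Sh[..., None, :, :])
    Y = (Y * _phases(la, tau2, -1)[..., None, :]) @ S[..., None, :, :]
    Y = Y * _phases(la, tau2, +1)[..., :, None] * _phases(lb, tau2, -1)[..., None, :]

    # contract: V[g1, g2] = d^-1 Re sum_{jm} X'[g1]_{jm} Y'[g2]_{mj}
    Xf = X.reshape(X.shape[:-2] + (d * d,))
    Yf = np.swapaxes(Y, -1, -2).reshape(Y.shape[:-2] + (d * d,))
    Z = Xf @ np.swapaxes(Yf, -1, -2)
    return Z.real / d
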