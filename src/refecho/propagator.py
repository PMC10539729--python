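"""Fully coherent echo-amplitude computation for a single cluster.

Ideal (instantaneous, electron-only) pulses, no relaxation terms, and a
high-temperature initial state (electron polarization, maximally mixed
nuclei).  The production path evaluates the normalized coherence-pathway
overlap trace formulas (see :mod:`refecho._kernels`); an independent
brute-force density-matrix oracle with explicit pulse rotation operators is
provided for verification on small baths.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np

from ._kernels import eig_pair, hahn_amplitudes, refocused_amplitudes
from .couplings import ClusterHamiltonians, CouplingSet, cluster_hamiltonians, spin_half_operators

__all__ = [
    "PulseSequence",
    "ClusterSignal",
    "hahn_echo",
    "refocused_echo",
    "exact_oracle",
]


@dataclasses.dataclass
class PulseSequence:
    """Echo sequence with its delay grid(s), in seconds.

    ``kind="hahn"``: pi/2 - tau - pi - tau - echo, grid ``tau1``.
    ``kind="refocused"``: pi/2 - tau1 - pi - (tau1+tau2) - pi - tau2 - echo,
    grids ``tau1`` and ``tau2``.
    """

    kind: str
    tau1: np.ndarray
    tau2: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in {"hahn", "refocused"}:
            raise ValueError("kind must be 'hahn' or 'refocused'")
        self.tau1 = self._check_grid(self.tau1, "tau1")
        if self.kind == "refocused":
            if self.tau2 is None:
                raise ValueError("refocused sequence requires a tau2 grid")
            self.tau2 = self._check_grid(self.tau2, "tau2")
        elif self.tau2 is not None:
            raise ValueError("hahn sequence takes a single tau grid")

    @staticmethod
    def _check_grid(grid, name) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        if grid.size == 0:
            raise ValueError(f"{name} grid is empty")
        if np.any(grid < 0):
            raise ValueError(f"{name} grid must be nonnegative")
        if grid.size > 1 and np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} grid must be strictly increasing")
        return grid

    @property
    def n_pi_pulses(self) -> int:
        return 1 if self.kind == "hahn" else 2


@dataclasses.dataclass
class ClusterSignal:
    """Echo amplitude of one cluster on the sequence grid (V = 1 at zero delay)."""

    indices: Tuple[int, ...]
    V: np.ndarray


def _check_hermitian(h: ClusterHamiltonians) -> None:
    for H in (h.H_alpha, h.H_beta):
        if not np.allclose(H, H.conj().T, atol=1e-9 * max(1.0, np.abs(H).max())):
            raise ValueError("cluster Hamiltonian is not Hermitian")


def hahn_echo(h: ClusterHamiltonians, tau_grid) -> ClusterSignal:
    """Two-pulse echo amplitude V(tau) of a cluster (normalized, real)."""
    _check_hermitian(h)
    tau = PulseSequence._check_grid(tau_grid, "tau")
    la, lb, S = eig_pair(h.H_alpha, h.H_beta)
    return ClusterSignal(indices=tuple(h.indices), V=hahn_amplitudes(la, lb, S, tau))


def refocused_echo(h: ClusterHamiltonians, tau1_grid, tau2_grid) -> ClusterSignal:
    """Refocused-echo amplitude V(tau1, tau2) of a cluster, shape (G1, G2)."""
    _check_hermitian(h)
    t1 = PulseSequence._check_grid(tau1_grid, "tau1")
    t2 = PulseSequence._check_grid(tau2_grid, "tau2")
    la, lb, S = eig_pair(h.H_alpha, h.H_beta)
    return ClusterSignal(indices=tuple(h.indices), V=refocused_amplitudes(la, lb, S, t1, t2))


# ---------------------------------------------------------------------------
# brute-force density-matrix oracle


def _full_hamiltonian(couplings: CouplingSet, indices: Sequence[int]) -> np.ndarray:
    """Rotating-frame Hamiltonian on the full 2^(N+1) electron+nuclei space."""
    n = len(indices)
    ops = spin_half_operators(n + 1)  # spin 0 = electron
    Ix, Iy, Iz = ops
    Sz = Iz[0]
    omega_I = couplings.field.omega_I
    H = np.zeros_like(Sz)
    for k, idx in enumerate(indices, start=1):
        H -= omega_I * Iz[k]
        H += Sz @ (
            couplings.A_zz[idx] * Iz[k]
            + couplings.A_zx[idx] * Ix[k]
            + couplings.A_zy[idx] * Iy[k]
        )
    for a in range(n):
        for c in range(a + 1, n):
            bmn = couplings.b[indices[a], indices[c]]
            H += bmn * (
                2.0 * (Ix[a + 1] @ Ix[c + 1] + Iy[a + 1] @ Iy[c + 1])
                - 4.0 * Iz[a + 1] @ Iz[c + 1]
            )
    return H


def _electron_rotation(angle: float, n_nuclei: int) -> np.ndarray:
    """exp(-i angle Sx) acting on the electron only."""
    c, s = np.cos(angle / 2.0), np.sin(angle / 2.0)
    r = np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)
    return np.kron(r, np.eye(2**n_nuclei, dtype=complex))


def exact_oracle(
    couplings: CouplingSet,
    sequence: PulseSequence,
    indices: Optional[Sequence[int]] = None,
    max_protons: int = 12,
) -> np.ndarray:
    """Brute-force echo amplitudes by explicit density-matrix propagation.

    Propagates the high-temperature deviation density matrix through ideal
    pi/2 and pi rotations about x on the electron and free evolution under
    the full electron+nuclear Hamiltonian; the echo is read out as the
    transverse electron coherence Tr[rho S+], normalized to its value at
    all-zero delays.  Exponential in the proton count; use for verification
    only.

    Returns the amplitude array (G,) for Hahn or (G1, G2) for refocused.
    """
    if indices is None:
        indices = list(range(couplings.n_protons))
    indices = [int(i) for i in indices]
    n = len(indices)
    if n > max_protons:
        raise ValueError(f"{n} protons exceed oracle cap of {max_protons}")

    H = _full_hamiltonian(couplings, indices)
    lam, V = np.linalg.eigh(H)
    ops = spin_half_operators(n + 1)
    Sz = ops[2][0]
    Splus = ops[0][0] + 1j * ops[1][0]
    R90 = _electron_rotation(np.pi / 2.0, n)
    R180 = _electron_rotation(np.pi, n)

    def U(t: float) -> np.ndarray:
        return (V * np.exp(-1j * lam * t)) @ V.conj().T

    def echo_seq(ts: Sequence[float]) -> complex:
        """pi/2 then alternate evolve/pi ending with a final evolution."""
        rho = R90 @ Sz @ R90.conj().T
        for dt in ts[:-1]:
            u = U(dt)
            rho = u @ rho @ u.conj().T
            rho = R180 @ rho @ R180.conj().T
        u = U(ts[-1])
        rho = u @ rho @ u.conj().T
        return np.trace(rho @ Splus)

    if sequence.kind == "hahn":
        ref = echo_seq([0.0, 0.0])
        out = np.empty(sequence.tau1.size, dtype=float)
        for i, t in enumerate(sequence.tau1):
            out[i] = (echo_seq([t, t]) / ref).real
        return out

    ref = echo_seq([0.0, 0.0, 0.0])
    out = np.empty((sequence.tau1.size, sequence.tau2.size), dtype=float)
    for i, t1 in enumerate(sequence.tau1):
        for j, t2 in enumerate(sequence.tau2):
            out[i, j] = (echo_seq([t1, t1 + t2, t2]) / ref).real
    return out


def exact_oracle_from_bath(bath, field, sequence: PulseSequence, max_protons: int = 12):
    """Convenience wrapper: couplings from a bath at the given field, then oracle."""
    from .couplings import build_coupling_set

    cs = build_coupling_set(bath, field)
    return exact_oracle(cs, sequence, max_protons=max_protons)
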