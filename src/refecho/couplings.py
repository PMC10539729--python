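"""Spin-Hamiltonian parameters from geometry.

Point-dipole electron-proton hyperfine couplings (secular A_zz and
pseudo-secular A_zx, A_zy components of the S_z-I coupling) and secular
proton-proton dipolar couplings b_mn, evaluated in the lab frame with z
along the applied field.  Cluster Hamiltonians are the two nuclear-spin
sub-Hamiltonians H_alpha / H_beta conditioned on the electron projection
m_S = +-1/2; the coupling Hamiltonian per manifold is

    H_+- = sum_n [ -omega_I I_z^n +- 1/2 (A_zz^n I_z^n + A_zx^n I_x^n + A_zy^n I_y^n) ]
           + sum_{m<n} b_mn (I+^m I-^n + I-^m I+^n - 4 I_z^m I_z^n)

with the electron Zeeman term omitted (constant within each manifold).
All couplings are angular frequencies (rad/s).
"""
from __future__ import annotations

import dataclasses
import functools
import pathlib
import warnings
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .bath import ProtonBath
from .constants import GAMMA_E, GAMMA_H, G_E, HBAR, MU0_OVER_4PI, TWO_PI

__all__ = [
    "FieldConfig",
    "CouplingSet",
    "ClusterHamiltonians",
    "hyperfine_tensor",
    "pair_coupling",
    "build_coupling_set",
    "cluster_hamiltonians",
    "spin_half_operators",
    "write_coupling_table",
]

_ANGSTROM = 1e-10


@dataclasses.dataclass(frozen=True)
class FieldConfig:
    """Static-field configuration.

    Parameters
    ----------
    B0 : float
        Applied magnetic field in tesla (default 3.38 T, W band).
    field_direction : (3,) array
        Unit vector of B0 in the molecular frame (lab z axis).
    g_e : float
        Electron g value.
    gamma_H : float
        Proton gyromagnetic ratio, rad/s/T.
    """

    B0: float = 3.38
    field_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    g_e: float = G_E
    gamma_H: float = GAMMA_H

    def __post_init__(self):
        n = np.asarray(self.field_direction, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("field_direction must be a unit vector")
        object.__setattr__(self, "field_direction", tuple(n / norm))

    @property
    def gamma_e(self) -> float:
        """Electron gyromagnetic ratio, rad/s/T (positive convention)."""
        from .constants import MU_B

        return self.g_e * MU_B / HBAR

    @property
    def omega_I(self) -> float:
        """Nuclear (proton) Zeeman angular frequency gamma_H * B0, rad/s."""
        return self.gamma_H * self.B0

    def with_direction(self, direction) -> "FieldConfig":
        return dataclasses.replace(self, field_direction=tuple(np.asarray(direction, float)))

    def transverse_axes(self) -> Tuple[np.ndarray, np.ndarray]:
        """A right-handed orthonormal (x, y) pair perpendicular to the field."""
        z = np.asarray(self.field_direction)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(z @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = ref - (ref @ z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        return x, y


@dataclasses.dataclass
class CouplingSet:
    """All spin-Hamiltonian parameters of a bath at one orientation.

    ``A_zz``, ``A_zx``, ``A_zy`` are per-proton hyperfine components and
    ``b`` is the symmetric proton-proton coupling matrix, all in rad/s.
    ``r_e``/``cos_theta_e`` hold the electron-proton geometry for reporting.
    """

    A_zz: np.ndarray
    A_zx: np.ndarray
    A_zy: np.ndarray
    b: np.ndarray
    field: FieldConfig
    r_e: Optional[np.ndarray] = None
    cos_theta_e: Optional[np.ndarray] = None
    #: orientation-independent pair dipolar coupling constant
    #: (mu0/4pi) gamma_H^2 hbar / r^3 in rad/s; used by the default
    #: cluster-threshold criterion (None for hand-built coupling sets)
    d_dip: Optional[np.ndarray] = None

    @property
    def n_protons(self) -> int:
        return self.A_zz.shape[0]

    def validate(self) -> None:
        if not np.allclose(self.b, self.b.T):
            raise ValueError("b matrix must be symmetric")
        if np.any(np.diag(self.b) != 0):
            raise ValueError("b diagonal must be zero")
        for arr in (self.A_zz, self.A_zx, self.A_zy, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite coupling encountered")


@dataclasses.dataclass
class ClusterHamiltonians:
    """Nuclear sub-Hamiltonians of one cluster for m_S = +1/2 (alpha) and
    -1/2 (beta), on the 2^size-dimensional cluster spin space."""

    indices: Tuple[int, ...]
    H_alpha: np.ndarray
    H_beta: np.ndarray

    @property
    def dim(self) -> int:
        return self.H_alpha.shape[0]


def _dipolar_prefactor_en(r_m: np.ndarray, field: FieldConfig) -> np.ndarray:
    """(mu0/4pi) gamma_e gamma_H hbar / r^3 in rad/s, r in metres."""
    return MU0_OVER_4PI * field.gamma_e * field.gamma_H * HBAR / r_m**3


def hyperfine_tensor(
    electron_position,
    proton_position,
    field: FieldConfig,
    exclusion_warn: float = 2.0,
) -> Tuple[float, float, float]:
    """Point-dipole hyperfine components (A_zz, A_zx, A_zy) in rad/s.

    Uses the single-nucleus axis convention: lab x in the plane spanned by
    the field and the electron-proton vector, so A_zy = 0 and
    A_zx = D_en * 3 sin(theta) cos(theta) with
    D_en = (mu0/4pi) gamma_e gamma_H hbar / r^3.  Only the magnitude
    sqrt(A_zx^2 + A_zy^2) is physical for a single nucleus.
    """
    rvec = np.asarray(proton_position, float) - np.asarray(electron_position, float)
    r = np.linalg.norm(rvec)
    if r == 0:
        raise ValueError("electron and proton positions coincide")
    if r < exclusion_warn:
        warnings.warn(
            f"electron-proton distance {r:.2f} A below {exclusion_warn} A: "
            "point-dipole approximation unreliable",
            stacklevel=2,
        )
    c = rvec @ np.asarray(field.field_direction) / r
    s = np.sqrt(max(0.0, 1.0 - c * c))
    D = _dipolar_prefactor_en(r * _ANGSTROM, field)
    return D * (3 * c * c - 1.0), D * 3.0 * s * c, 0.0


def pair_coupling(pos_m, pos_n, field: FieldConfig) -> float:
    """Secular proton-proton coupling b_mn in rad/s.

    b_mn = (mu0/4pi) gamma_H^2 hbar (3 cos^2 theta - 1) / (4 r^3), chosen so
    that b_mn (I+I- + I-I+ - 4 IzIz) is the secular nuclear dipolar
    Hamiltonian of the pair.
    """
    rvec = np.asarray(pos_n, float) - np.asarray(pos_m, float)
    r = np.linalg.norm(rvec)
    if r == 0:
        raise ValueError("coincident nuclei")
    c = rvec @ np.asarray(field.field_direction) / r
    return (
        MU0_OVER_4PI * field.gamma_H**2 * HBAR * (3 * c * c - 1.0) / (4.0 * (r * _ANGSTROM) ** 3)
    )


def build_coupling_set(
    bath: ProtonBath,
    field: FieldConfig,
    orientation=None,
) -> CouplingSet:
    """Evaluate all hyperfine and pair couplings of a bath, vectorized.

    Parameters
    ----------
    orientation : scipy.spatial.transform.Rotation, optional
        Molecular-frame rotation applied to all electron-relative positions
        before evaluating the couplings.

    Notes
    -----
    Unlike :func:`hyperfine_tensor` (per-nucleus axis convention), the
    pseudo-secular components here are resolved on a single pair of lab
    transverse axes shared by all nuclei, which is required for clusters;
    per-nucleus magnitudes agree with :func:`hyperfine_tensor`.
    """
    if bath.n_protons == 0:
        raise ValueError("bath is empty")
    pos = bath.relative_positions()
    if orientation is not None:
        pos = orientation.apply(pos)

    z = np.asarray(field.field_direction)
    xhat, yhat = field.transverse_axes()

    r = np.linalg.norm(pos, axis=1)
    u = pos / r[:, None]
    c = u @ z
    D = _dipolar_prefactor_en(r * _ANGSTROM, field)
    A_zz = D * (3 * c * c - 1.0)
    A_zx = D * 3.0 * c * (u @ xhat)
    A_zy = D * 3.0 * c * (u @ yhat)

    diff = pos[:, None, :] - pos[None, :, :]
    r_nn = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(r_nn, np.inf)
    c_nn = (diff @ z) / r_nn
    b = (
        MU0_OVER_4PI
        * field.gamma_H**2
        * HBAR
        * (3 * c_nn * c_nn - 1.0)
        / (4.0 * (r_nn * _ANGSTROM) ** 3)
    )
    np.fill_diagonal(b, 0.0)
    d_dip = MU0_OVER_4PI * field.gamma_H**2 * HBAR / (r_nn * _ANGSTROM) ** 3
    np.fill_diagonal(d_dip, 0.0)

    return CouplingSet(
        A_zz=A_zz, A_zx=A_zx, A_zy=A_zy, b=b, field=field, r_e=r, cos_theta_e=c,
        d_dip=d_dip,
    )


@functools.lru_cache(maxsize=8)
def spin_half_operators(n_spins: int):
    """Single-spin I_x, I_y, I_z embedded in an n-spin product space.

    Returns three tuples (Ix, Iy, Iz) of length ``n_spins`` of dense
    (2^n, 2^n) complex arrays.
    """
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    eye = np.eye(2, dtype=complex)

    def embed(op, k):
        mats = [op if i == k else eye for i in range(n_spins)]
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    Ix = tuple(embed(sx, k) for k in range(n_spins))
    Iy = tuple(embed(sy, k) for k in range(n_spins))
    Iz = tuple(embed(sz, k) for k in range(n_spins))
    return Ix, Iy, Iz


def cluster_hamiltonians(
    couplings: CouplingSet,
    cluster: Sequence[int],
    field: Optional[FieldConfig] = None,
) -> ClusterHamiltonians:
    """Assemble H_alpha / H_beta for a cluster of proton indices."""
    field = field or couplings.field
    cluster = tuple(int(i) for i in cluster)
    n = len(cluster)
    if any(i < 0 or i >= couplings.n_protons for i in cluster):
        raise IndexError("cluster index out of range")
    Ix, Iy, Iz = spin_half_operators(n)

    H_bath = np.zeros((2**n, 2**n), dtype=complex)
    H_hf = np.zeros_like(H_bath)
    for k, idx in enumerate(cluster):
        H_bath -= field.omega_I * Iz[k]
        H_hf += 0.5 * (
            couplings.A_zz[idx] * Iz[k]
            + couplings.A_zx[idx] * Ix[k]
            + couplings.A_zy[idx] * Iy[k]
        )
    for a in range(n):
        for bidx in range(a + 1, n):
            bmn = couplings.b[cluster[a], cluster[bidx]]
            H_bath += bmn * (
                2.0 * (Ix[a] @ Ix[bidx] + Iy[a] @ Iy[bidx]) - 4.0 * Iz[a] @ Iz[bidx]
            )
    return ClusterHamiltonians(indices=cluster, H_alpha=H_bath + H_hf, H_beta=H_bath - H_hf)


def write_coupling_table(couplings: CouplingSet, path: Union[str, pathlib.Path]) -> None:
    """Export per-proton and per-pair couplings as a plain-text table.

    Frequencies are reported in MHz (hyperfine) and kHz (pair couplings).
    """
    lines = ["# per-proton hyperfine couplings", "# id  r_A  cos_theta  Azz_MHz  Aperp_MHz"]
    perp = np.hypot(couplings.A_zx, couplings.A_zy)
    r = couplings.r_e if couplings.r_e is not None else np.full(couplings.n_protons, np.nan)
    ct = (
        couplings.cos_theta_e
        if couplings.cos_theta_e is not None
        else np.full(couplings.n_protons, np.nan)
    )
    for i in range(couplings.n_protons):
        lines.append(
            f"{i:6d} {r[i]:10.4f} {ct[i]:10.6f} "
            f"{couplings.A_zz[i] / TWO_PI / 1e6:14.6e} {perp[i] / TWO_PI / 1e6:14.6e}"
        )
    lines.append("# per-pair couplings")
    lines.append("# m  n  b_kHz")
    for m in range(couplings.n_protons):
        for n in range(m + 1, couplings.n_protons):
            lines.append(f"{m:6d} {n:6d} {couplings.b[m, n] / TWO_PI / 1e3:14.6e}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
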