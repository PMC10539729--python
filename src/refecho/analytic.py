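"""Linked-cluster analytics of the refocused echo decay.

The leading (second-order in the nuclear flip-flop coupling b_mn) term of
the refocused-echo amplitude is

    <V2>(tau1, tau2) = - sum_{m != n} (2 b_mn^2 / w_mn^2)
                         (cos w_mn tau1 - cos w_mn tau2)^2,

with w_mn = (A_m - A_n)/2 the difference of the secular hyperfine
couplings; the sum runs over ordered pairs.  <V2> is <= 0 everywhere and
vanishes on the Carr-Purcell diagonal tau1 = tau2.  Collecting higher-order
terms into a residual factor f gives the linked-cluster factorization

    V(tau1, tau2) = exp(<V2>) * f(tau1, tau2),

where exp(<V2>) carries the dynamic-decoupling structure (maximal on the
diagonal) and f predominantly the decay with total evolution time.  The
ordered-pair prefactor convention is locked by a perturbative oracle:
for a single pair with pseudo-secular terms off, ln V -> <V2> with an
error of order b^3 as b -> 0 (asserted in the test suite).

The ridge utilities extract the loci of slice-wise echo maxima (the
optimal tau1 for each tau2) and the delay at which the ridge starts to
deviate from the diagonal.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

from .analysis_io import EchoMap2D, RidgeCurve
from .couplings import CouplingSet

__all__ = [
    "AnalyticFactorization",
    "v2_term",
    "v2_map",
    "factorize",
    "ridge",
    "deviation_onset",
]


@dataclasses.dataclass
class AnalyticFactorization:
    """<V2> map and residual factor f with V = exp(<V2>) * f."""

    V2: EchoMap2D
    f: EchoMap2D

    def reconstruct(self) -> np.ndarray:
        """exp(<V2>) * f, equal to the input V map."""
        return np.exp(self.V2.V) * self.f.V


def _pair_terms(couplings: CouplingSet) -> Tuple[np.ndarray, np.ndarray]:
    """(w_mn, b_mn) over unordered pairs m < n, rad/s."""
    n = couplings.n_protons
    iu = np.triu_indices(n, k=1)
    w = 0.5 * (couplings.A_zz[iu[0]] - couplings.A_zz[iu[1]])
    b = couplings.b[iu]
    return w, b


def v2_term(couplings: CouplingSet, tau1: float, tau2: float) -> float:
    """<V2> at a single (tau1, tau2) point (dimensionless, <= 0).

    Degenerate pairs (w_mn = 0) contribute 0, their continuous limit.
    """
    return float(v2_map(couplings, np.atleast_1d(tau1), np.atleast_1d(tau2))[0, 0])


def v2_map(couplings: CouplingSet, tau1: np.ndarray, tau2: np.ndarray) -> np.ndarray:
    """<V2> on the full (tau1, tau2) grid, shape (G1, G2).

    Vectorized over the ordered-pair sum (each unordered pair enters
    twice; the two ordered terms are equal since w_mn is squared).
    """
    tau1 = np.atleast_1d(np.asarray(tau1, dtype=float))
    tau2 = np.atleast_1d(np.asarray(tau2, dtype=float))
    w, b = _pair_terms(couplings)
    keep = (w != 0.0) & (b != 0.0)
    w, b = w[keep], b[keep]
    if w.size == 0:
        return np.zeros((tau1.size, tau2.size))
    # ordered-pair sum = 2 x unordered sum
    amp = 4.0 * b**2 / w**2  # (P,)
    c1 = np.cos(np.outer(w, tau1))  # (P, G1)
    c2 = np.cos(np.outer(w, tau2))  # (P, G2)
    diff = c1[:, :, None] - c2[:, None, :]
    return -np.einsum("p,pij->ij", amp, diff**2)


def factorize(V: EchoMap2D, couplings: Optional[CouplingSet] = None,
              V2: Optional[np.ndarray] = None) -> AnalyticFactorization:
    """Split an echo map into exp(<V2>) and the residual factor f = V * exp(-<V2>).

    Either a coupling set (from which <V2> is evaluated analytically) or a
    precomputed <V2> array on the same grid must be given.  Since
    exp(-<V2>) >= 1 there is no division hazard.
    """
    if (couplings is None) == (V2 is None):
        raise ValueError("give exactly one of couplings or V2")
    if V2 is None:
        V2 = v2_map(couplings, V.tau1, V.tau2)
    V2 = np.asarray(V2, dtype=float)
    if V2.shape != V.V.shape:
        raise ValueError("V2 map and V map must share one grid")
    f = V.V * np.exp(-V2)
    meta = dict(V.meta)
    return AnalyticFactorization(
        V2=EchoMap2D(V.tau1, V.tau2, V2, normalized=False, meta=meta),
        f=EchoMap2D(V.tau1, V.tau2, f, normalized=V.normalized, meta=meta),
    )


def _refine_parabolic(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Three-point parabolic sub-grid refinement of an interior maximum."""
    if i == 0 or i == x.size - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[i + 1] - x[i - 1]) / 2.0)


def ridge(emap: EchoMap2D, flat_rtol: float = 1e-12) -> Tuple[RidgeCurve, RidgeCurve]:
    """Slice-wise maximum loci of an echo map.

    For every tau2 the optimal tau1* = argmax_tau1 V(tau1, tau2) with
    three-point parabolic refinement; ties break toward smaller tau1 and
    all-flat slices yield tau1* = 0 with a ``"flat"`` flag.  Returns the
    primary ridge (tau1* vs tau2) and the transposed ridge (tau2* vs tau1).
    """

    def _one_axis(m: EchoMap2D) -> RidgeCurve:
        tau1_star = np.empty(m.tau2.size)
        flags = []
        step = float(np.median(np.diff(m.tau1))) if m.tau1.size > 1 else 0.0
        for j in range(m.tau2.size):
            v = m.V[:, j]
            span = v.max() - v.min()
            if span <= flat_rtol * max(1.0, np.abs(v).max()):
                tau1_star[j] = 0.0
                flags.append("flat")
                continue
            i = int(np.argmax(v))  # first maximum = smallest tau1 on ties
            tau1_star[j] = _refine_parabolic(m.tau1, v, i)
            flags.append("boundary" if i in (0, m.tau1.size - 1) else "ok")
        return RidgeCurve(
            tau2=m.tau2.copy(), tau1_star=tau1_star, flags=tuple(flags), axis_step=step
        )

    return _one_axis(emap), _one_axis(emap.transposed())


def deviation_onset(curve: RidgeCurve, tolerance: Optional[float] = None) -> Optional[float]:
    """Smallest tau2 at which the ridge persistently leaves the diagonal.

    The onset is the first tau2 for which tau2 - tau1* exceeds
    ``tolerance`` (default: one tau1 grid step) for that and all larger
    tau2 on the grid.  Returns None when no persistent deviation exists.
    """
    if tolerance is None:
        tolerance = curve.axis_step
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    deviated = (curve.tau2 - curve.tau1_star) > tolerance
    if not deviated.any():
        return None
    # persistent: deviated from some index onward
    idx = np.flatnonzero(~deviated)
    first_persistent = 0 if idx.size == 0 else int(idx[-1]) + 1
    if first_persistent >= curve.tau2.size:
        return None
    return float(curve.tau2[first_persistent])
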