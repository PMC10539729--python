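"""Decay-curve and decay-map analysis plus plain-text file I/O.

Provides the 2D echo-map container, slice-wise normalization, the
stretched-exponential phase-memory fit V(t) = V0 exp[-(t/TM)^x] (with t the
total evolution time, 2*tau for a Hahn echo), the DEER SNR utility, and
readers/writers for two-column trace files and CSV echo maps (time unit in
files: microseconds; in memory: seconds).
"""
from __future__ import annotations

import dataclasses
import pathlib
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EchoMap2D",
    "RidgeCurve",
    "StretchedExpFit",
    "SNRParams",
    "stretched_exp_fit",
    "normalize_slices",
    "snr_estimate",
    "read_trace",
    "write_trace",
    "read_map",
    "write_map",
]

_US = 1e-6


@dataclasses.dataclass
class EchoMap2D:
    """Echo amplitude V on a (tau1, tau2) grid.

    ``V[i, j]`` is the amplitude at ``tau1[i]``, ``tau2[j]`` (seconds).
    ``normalized`` marks maps with V = 1 at zero delay (or slice-normalized
    maps); ``meta`` carries simulation provenance.
    """

    tau1: np.ndarray
    tau2: np.ndarray
    V: np.ndarray
    normalized: bool = False
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.tau1 = np.atleast_1d(np.asarray(self.tau1, dtype=float))
        self.tau2 = np.atleast_1d(np.asarray(self.tau2, dtype=float))
        self.V = np.asarray(self.V, dtype=float)
        for name, ax in (("tau1", self.tau1), ("tau2", self.tau2)):
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError(f"non-monotonic {name} axis")
        if self.V.shape != (self.tau1.size, self.tau2.size):
            raise ValueError(
                f"V shape {self.V.shape} inconsistent with axes "
                f"({self.tau1.size}, {self.tau2.size})"
            )
        if (
            self.normalized
            and self.tau1[0] == 0.0
            and self.tau2[0] == 0.0
            and abs(self.V[0, 0] - 1.0) > 1e-9
        ):
            raise ValueError("normalized map must have V(0,0) = 1")

    def transposed(self) -> "EchoMap2D":
        return EchoMap2D(self.tau2, self.tau1, self.V.T, self.normalized, dict(self.meta))


@dataclasses.dataclass
class RidgeCurve:
    """Loci of slice-wise maxima: optimal tau1*(tau2) (seconds).

    ``flags`` marks degenerate slices ("flat") or boundary maxima
    ("boundary"); ``axis_step`` is the tau1 grid step used as the default
    deviation tolerance.
    """

    tau2: np.ndarray
    tau1_star: np.ndarray
    flags: Tuple[str, ...]
    axis_step: float = 0.0

    def __post_init__(self):
        self.tau2 = np.atleast_1d(np.asarray(self.tau2, dtype=float))
        self.tau1_star = np.atleast_1d(np.asarray(self.tau1_star, dtype=float))
        if self.tau2.size != self.tau1_star.size:
            raise ValueError("tau2 and tau1_star must have equal length")
        if len(self.flags) != self.tau2.size:
            raise ValueError("one flag per ridge point required")


@dataclasses.dataclass
class StretchedExpFit:
    """Result of fitting V(t) = V0 exp[-(t/TM)^x].

    ``TM`` is in seconds; ``*_err`` are 1-sigma estimates from the local
    curvature of the least-squares objective; ``residual_norm`` is the rms
    residual.
    """

    V0: float
    TM: float
    x: float
    V0_err: float
    TM_err: float
    x_err: float
    residual_norm: float

    def __post_init__(self):
        if self.TM <= 0:
            raise ValueError("TM must be positive")
        if not 0 < self.x <= 4:
            raise ValueError("stretch exponent out of range (0, 4]")
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")

    def report(self) -> str:
        return (
            f"V0 = {self.V0:.6g} +- {self.V0_err:.2g}\n"
            f"TM = {self.TM / _US:.6g} +- {self.TM_err / _US:.2g} us\n"
            f"x  = {self.x:.6g} +- {self.x_err:.2g}\n"
            f"rms residual = {self.residual_norm:.3g}"
        )


@dataclasses.dataclass
class SNRParams:
    """Inputs of the relative DEER SNR estimate."""

    decay: StretchedExpFit
    modulation_depth: float
    T1: float
    tau: float

    def __post_init__(self):
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")
        if self.T1 <= 0:
            raise ValueError("T1 must be positive")


def _stretched(t, V0, TM, x):
    return V0 * np.exp(-np.power(t / TM, x))


def stretched_exp_fit(
    t: np.ndarray,
    V: np.ndarray,
    x_starts: Tuple[float, ...] = (0.8, 1.5, 2.5),
) -> StretchedExpFit:
    """Least-squares stretched-exponential fit of an echo decay.

    Parameters
    ----------
    t : array
        Total evolution time in seconds (2*tau for a Hahn echo); must be
        positive and contain at least 6 points.
    V : array
        Echo amplitudes.
    x_starts : tuple
        Deterministic multi-start values for the stretch exponent; TM is
        initialized from the 1/e crossing of the trace.

    Raises
    ------
    RuntimeError
        If no start converges.
    ValueError
        For degenerate (non-decaying) traces or invalid inputs.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 points to fit")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.all(np.isfinite(V)):
        raise ValueError("amplitudes must be finite")
    v0_guess = float(V[np.argmin(t)])
    if v0_guess <= 0 or V[np.argmax(t)] >= 0.95 * v0_guess:
        raise ValueError("trace does not decay; stretched-exponential fit is degenerate")

    below = t[V <= v0_guess / np.e]
    tm_guess = float(below.min()) if below.size else float(t.max())

    best = None
    for x0 in x_starts:
        try:
            popt, pcov = curve_fit(
                _stretched,
                t,
                V,
                p0=(v0_guess, tm_guess, x0),
                bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 4.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = V - _stretched(t, *popt)
        cost = float(resid @ resid)
        if best is None or cost < best[0]:
            best = (cost, popt, pcov)
    if best is None:
        raise RuntimeError("stretched-exponential fit did not converge from any start")
    cost, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return StretchedExpFit(
        V0=float(popt[0]),
        TM=float(popt[1]),
        x=float(popt[2]),
        V0_err=float(perr[0]),
        TM_err=float(perr[1]),
        x_err=float(perr[2]),
        residual_norm=float(np.sqrt(cost / t.size)),
    )


def normalize_slices(emap: EchoMap2D, axis: str = "tau1") -> EchoMap2D:
    """Divide each slice along the chosen axis by its own maximum.

    ``axis="tau1"`` normalizes each fixed-tau2 slice (the presentation used
    for optimal-tau1 ridge extraction); all-zero slices are left unchanged
    and flagged in ``meta["zero_slices"]``.
    """
    if axis not in {"tau1", "tau2"}:
        raise ValueError("axis must be 'tau1' or 'tau2'")
    V = emap.V.copy()
    zero_slices = []
    if axis == "tau1":
        for j in range(emap.tau2.size):
            m = np.abs(V[:, j]).max()
            if m == 0:
                zero_slices.append(j)
            else:
                V[:, j] = V[:, j] / V[:, j].max()
    else:
        for i in range(emap.tau1.size):
            m = np.abs(V[i]).max()
            if m == 0:
                zero_slices.append(i)
            else:
                V[i] = V[i] / V[i].max()
    meta = dict(emap.meta)
    meta["slice_normalized"] = axis
    if zero_slices:
        meta["zero_slices"] = zero_slices
    # slice-normalized maps no longer carry the V(0,0) = 1 invariant
    normalized = bool(
        emap.tau1[0] == 0.0 and emap.tau2[0] == 0.0 and abs(V[0, 0] - 1.0) < 1e-9
    )
    return EchoMap2D(emap.tau1, emap.tau2, V, normalized=normalized, meta=meta)


def snr_estimate(p: SNRParams) -> float:
    """Relative DEER SNR: V0 * lambda * exp[-(2 tau / TM)^x] / sqrt(T1).

    Constant instrumental factors are dropped; only ratios between
    parameter sets are meaningful.
    """
    d = p.decay
    return float(
        d.V0 * p.modulation_depth * np.exp(-((2.0 * p.tau / d.TM) ** d.x)) / np.sqrt(p.T1)
    )


# ---------------------------------------------------------------------------
# file formats


def write_trace(path: Union[str, pathlib.Path], t: np.ndarray, V: np.ndarray, header: str = "") -> None:
    """Write a two-column (time_us, amplitude) plain-text trace."""
    t = np.asarray(t, dtype=float) / _US
    body = "\n".join(f"{ti:.10g} {vi:.17g}" for ti, vi in zip(t, np.asarray(V, float)))
    head = "".join(f"# {line}\n" for line in ([*header.splitlines()] + ["time_us amplitude"]))
    pathlib.Path(path).write_text(head + body + "\n")


def read_trace(path: Union[str, pathlib.Path]) -> Tuple[np.ndarray, np.ndarray]:
    """Read a two-column plain-text trace; returns (time_s, amplitude).

    Lines starting with ``#`` or ``%`` are comments.  Times in the file are
    microseconds.
    """
    data = np.loadtxt(path, comments=("#", "%"), ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, amplitude)")
    return data[:, 0] * _US, data[:, 1]


def write_map(path: Union[str, pathlib.Path], emap: EchoMap2D) -> None:
    """Write an echo map as CSV: tau1 header row (us), tau2 label column (us)."""
    df = pd.DataFrame(
        emap.V.T, index=emap.tau2 / _US, columns=emap.tau1 / _US
    )
    df.index.name = "tau2_us\\tau1_us"
    df.to_csv(path, float_format="%.17g")


def read_map(path: Union[str, pathlib.Path]) -> EchoMap2D:
    """Read a CSV echo map written by :func:`write_map`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    try:
        tau1 = np.asarray([float(c) for c in df.columns])
        tau2 = np.asarray([float(i) for i in df.index])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed header/axis labels") from exc
    for name, ax in (("tau1", tau1), ("tau2", tau2)):
        if ax.size > 1 and np.any(np.diff(ax) <= 0):
            raise ValueError(f"{path}: non-monotonic {name} axis")
    V = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(V)):
        raise ValueError(f"{path}: non-numeric or missing map values")
    emap = EchoMap2D(tau1 * _US, tau2 * _US, V)
    emap.normalized = bool(
        tau1[0] == 0.0 and tau2[0] == 0.0 and abs(V[0, 0] - 1.0) < 1e-9
    )
    return emap
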