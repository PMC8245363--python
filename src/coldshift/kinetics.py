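"""Four-reaction kinetic model of gene expression.

The model tracks one mRNA and one protein species governed by four
mass-action reactions: constitutive transcription (rate ``k1``,
concentration per time), first-order mRNA degradation (``k2``),
translation proportional to mRNA (``k3``) and first-order protein
degradation (``k4``)::

    d[mRNA]/dt    = k1 - k2 * [mRNA]
    d[Protein]/dt = k3 * [mRNA] - k4 * [Protein]

Being linear, the system has a unique globally attracting steady state
(``mRNA_ss = k1/k2``, ``Protein_ss = k1*k3/(k2*k4)``) and an exact
two-exponential solution, both exposed here alongside a numerical
integrator for piecewise-constant rate protocols (temperature shifts).

All times and concentrations are in arbitrary units, matching how the
rate constants are specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "SystemState",
    "SteadyState",
    "ShiftProtocol",
    "Trajectory",
    "derivatives",
    "steady_state",
    "closed_form",
    "integrate",
    "integrate_constant",
    "is_steady",
]

#: default shift time of the cold-shift protocols (a.u.)
DEFAULT_SHIFT_TIME = 400.0
#: default total simulated duration (a.u.)
DEFAULT_DURATION = 1200.0

# threshold below which k2 and k4 are treated as equal (degenerate
# double-exponential collapses to a t*exp(-k t) term)
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class RateConstants:
    """The four rate parameters defining one temperature condition.

    Parameters
    ----------
    k1 : transcription rate (concentration / time, a.u.)
    k2 : mRNA degradation rate constant (1 / time, a.u.)
    k3 : translation rate constant (1 / time, a.u.)
    k4 : protein degradation rate constant (1 / time, a.u.)

    All four must be strictly positive and finite.
    """

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"rate constant {name} must be strictly positive and "
                    f"finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4], dtype=float)

    def scaled(self, factor: float) -> "RateConstants":
        """All four rates multiplied by a common positive factor."""
        return RateConstants(
            self.k1 * factor, self.k2 * factor, self.k3 * factor, self.k4 * factor
        )

    def replace(self, **kwargs: float) -> "RateConstants":
        vals = {k: getattr(self, k) for k in ("k1", "k2", "k3", "k4")}
        vals.update(kwargs)
        return RateConstants(**vals)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous concentrations of the two species."""

    mrna: float
    protein: float
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mrna", "protein", "time"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.mrna < 0 or self.protein < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the model for one rate set."""

    mrna_ss: float
    protein_ss: float

    def as_state(self, time: float = 0.0) -> SystemState:
        return SystemState(self.mrna_ss, self.protein_ss, time)


@dataclass(frozen=True)
class ShiftProtocol:
    """One temperature-shift experiment: pre rates, shift time, post rates."""

    rates_pre: RateConstants
    rates_post: RateConstants
    shift_time: float = DEFAULT_SHIFT_TIME
    duration: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        if not (0.0 < self.shift_time < self.duration):
            raise ValueError(
                f"need 0 < shift_time < duration, got shift_time="
                f"{self.shift_time}, duration={self.duration}"
            )


@dataclass(frozen=True)
class Trajectory:
    """Time grid with mRNA and protein concentration series."""

    times: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mrna, dtype=float)
        p = np.asarray(self.protein, dtype=float)
        if not (t.shape == m.shape == p.shape) or t.ndim != 1 or t.size == 0:
            raise ValueError("times, mrna, protein must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mrna", m)
        object.__setattr__(self, "protein", p)

    def final_state(self) -> SystemState:
        return SystemState(
            float(max(self.mrna[-1], 0.0)),
            float(max(self.protein[-1], 0.0)),
            float(self.times[-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "mrna": self.mrna, "protein": self.protein}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["time"].to_numpy(), df["mrna"].to_numpy(), df["protein"].to_numpy()
        )


def derivatives(
    state: SystemState, rates: RateConstants
) -> tuple[float, float]:
    """Right-hand side of the model ODEs at one state.

    Returns ``(d_mrna, d_protein) = (k1 - k2*m, k3*m - k4*p)``.
    """
    m, p = state.mrna, state.protein
    if not (math.isfinite(m) and math.isfinite(p)):
        raise ValueError("state concentrations must be finite")
    return (rates.k1 - rates.k2 * m, rates.k3 * m - rates.k4 * p)


def steady_state(rates: RateConstants) -> SteadyState:
    """Exact fixed point: ``mRNA_ss = k1/k2``, ``Protein_ss = k1*k3/(k2*k4)``."""
    return SteadyState(
        mrna_ss=rates.k1 / rates.k2,
        protein_ss=(rates.k1 * rates.k3) / (rates.k2 * rates.k4),
    )


def _closed_form_arrays(
    rates: RateConstants, m0: float, p0: float, dt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution at elapsed times ``dt >= 0`` from (m0, p0).

    mRNA relaxes single-exponentially with rate k2; protein is the
    superposition of its own k4 relaxation and the driven k2 term.  When
    k2 == k4 the driven term degenerates to ``k3*(m0-mss)*dt*exp(-k2*dt)``.
    """
    ss = steady_state(rates)
    k2, k3, k4 = rates.k2, rates.k3, rates.k4
    dm0 = m0 - ss.mrna_ss
    e2 = np.exp(-k2 * dt)
    mrna = ss.mrna_ss + dm0 * e2

    e4 = np.exp(-k4 * dt)
    if abs(k2 - k4) < _DEGENERATE_RTOL * max(k2, k4):
        driven = k3 * dm0 * dt * e2
    else:
        driven = k3 * dm0 / (k4 - k2) * (e2 - e4)
    protein = ss.protein_ss + (p0 - ss.protein_ss) * e4 + driven
    return mrna, protein


def closed_form(rates: RateConstants, init: SystemState, t: float) -> SystemState:
    """Exact analytic solution of the model at absolute time ``t``.

    ``t`` must not precede the initial state's time.  Serves as the
    analytic oracle for the numerical integrator.
    """
    if t < init.time:
        raise ValueError(f"t={t} precedes initial time {init.time}")
    dt = np.array([t - init.time], dtype=float)
    m, p = _closed_form_arrays(rates, init.mrna, init.protein, dt)
    return SystemState(float(max(m[0], 0.0)), float(max(p[0], 0.0)), t)


def _integrate_segment(
    rates: RateConstants,
    y0: Sequence[float],
    t0: float,
    t1: float,
    t_eval: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """solve_ivp over one constant-rate segment; returns (ys at t_eval, y at t1)."""

    def rhs(_t, y):
        return [rates.k1 - rates.k2 * y[0], rates.k3 * y[0] - rates.k4 * y[1]]

    sol = solve_ivp(
        rhs,
        (t0, t1),
        list(y0),
        method="DOP853",
        t_eval=t_eval if t_eval.size else None,
        rtol=1e-8,
        atol=1e-10,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y_end = sol.y[:, -1] if t_eval.size and t_eval[-1] == t1 else None
    if y_end is None:
        # integrate again without t_eval truncation to recover the endpoint
        sol_end = solve_ivp(
            rhs, (t0, t1), list(y0), method="DOP853", rtol=1e-8, atol=1e-10
        )
        if not sol_end.success:
            raise RuntimeError(f"ODE integration failed: {sol_end.message}")
        y_end = sol_end.y[:, -1]
    ys = sol.y if t_eval.size else np.empty((2, 0))
    return ys, y_end


def integrate(
    protocol: ShiftProtocol,
    init: SystemState | None = None,
    n_points: int = 601,
) -> Trajectory:
    """Numerically integrate a shift protocol on a uniform output grid.

    Rates are ``rates_pre`` on [0, shift_time] and ``rates_post``
    afterwards; concentrations are continuous at the shift.  The default
    initial condition is the empty system (no mRNA, no protein).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if init is None:
        init = SystemState(0.0, 0.0, 0.0)

    ts = np.linspace(0.0, protocol.duration, n_points)
    pre_mask = ts <= protocol.shift_time
    ys_pre, y_shift = _integrate_segment(
        protocol.rates_pre,
        (init.mrna, init.protein),
        0.0,
        protocol.shift_time,
        ts[pre_mask],
    )
    ys_post, _ = _integrate_segment(
        protocol.rates_post, y_shift, protocol.shift_time, protocol.duration,
        ts[~pre_mask],
    )
    ys = np.hstack([ys_pre, ys_post])
    # clip tiny negative excursions from integrator error
    ys = np.maximum(ys, 0.0)
    return Trajectory(ts, ys[0], ys[1])


def integrate_constant(
    rates: RateConstants,
    init: SystemState,
    duration: float,
    n_points: int = 601,
) -> Trajectory:
    """Integrate with a single constant rate set (no shift)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if duration <= 0:
        raise ValueError("duration must be positive")
    ts = np.linspace(0.0, duration, n_points)
    ys, _ = _integrate_segment(rates, (init.mrna, init.protein), 0.0, duration, ts)
    ys = np.maximum(ys, 0.0)
    return Trajectory(ts, ys[0], ys[1])


def is_steady(trajectory: Trajectory, rel_tol: float = 1e-4) -> bool:
    """True iff both species are flat over the final 10% of the window.

    "Flat" means the spread (max - min) over the tail, relative to the
    tail mean (or to 1 if the mean is ~0), is below ``rel_tol``.
    """
    t = trajectory.times
    tail = t >= t[-1] - 0.1 * (t[-1] - t[0])
    for series in (trajectory.mrna, trajectory.protein):
        seg = series[tail]
        scale = max(abs(float(np.mean(seg))), 1e-12)
        if (seg.max() - seg.min()) / scale >= rel_tol:
            return False
    return True
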