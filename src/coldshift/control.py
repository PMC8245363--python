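"""Compensatory control-point analysis.

After a cold shift hits production harder than degradation, the
chloroplast can restore the old protein steady state by adjusting any of
the four rates: transcription (F1), mRNA degradation (F2), translation
(F3) or protein degradation (F4), singly or in combination.  Because the
steady states are rational in the rate constants, the required
fold-changes invert in closed form — with the 14 degC rate set the answer
is a 25-fold increase of k1 or k3, or a 25-fold decrease of k2 or k4, and
joint strategies only need their fold-changes to multiply to 25.

The module also quantifies the trade-offs: the mRNA overshoot that
transcription-only control drags along, the transition time between
steady states, transient overshoot/dip behavior when control is applied
immediately at the shift versus after settling, and the cost-versus-speed
Pareto front where the production up-factor proxies ATP expenditure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    RateConstants,
    SteadyState,
    Trajectory,
    integrate_constant,
    steady_state,
)

__all__ = [
    "ControlPoint",
    "ControlSolution",
    "ParetoPoint",
    "required_fold_change",
    "mrna_side_effect",
    "combined_control",
    "transition_time",
    "response_simulation",
    "pareto_front",
    "degradation_stop_response",
    "control_report",
]

_SPLIT_RTOL = 1e-9


class ControlPoint(enum.Enum):
    """The four rates the cell could regulate to compensate a cold shift."""

    F1 = "transcription"
    F2 = "mrna_degradation"
    F3 = "translation"
    F4 = "protein_degradation"

    @property
    def rate_name(self) -> str:
        return {"F1": "k1", "F2": "k2", "F3": "k3", "F4": "k4"}[self.name]

    @property
    def is_degradation(self) -> bool:
        return self in (ControlPoint.F2, ControlPoint.F4)


@dataclass(frozen=True)
class ControlSolution:
    """One compensation strategy and its consequences.

    ``fold_changes`` maps each adjusted control point to the
    multiplicative factor applied to its rate constant (>1 up-regulation,
    <1 down-regulation).  ``transition_time_tau`` is the protein-level
    transition time of the adjusted system.
    """

    points: frozenset[ControlPoint]
    fold_changes: dict[ControlPoint, float]
    adjusted_rates: RateConstants
    achieved_ss: SteadyState
    transition_time_tau: float

    def fold_magnitude(self, point: ControlPoint) -> float:
        """Fold-change as a magnitude >= 1 (25 for both k1*25 and k4/25)."""
        f = self.fold_changes[point]
        return f if f >= 1.0 else 1.0 / f


@dataclass(frozen=True)
class ParetoPoint:
    """One point on the cost-vs-speed front."""

    up_factor: float
    down_factor: float
    tau: float


def _adjust(rates: RateConstants, fold_changes: dict[ControlPoint, float]
            ) -> RateConstants:
    kw = {p.rate_name: getattr(rates, p.rate_name) * f
          for p, f in fold_changes.items()}
    return rates.replace(**kw)


def _solution(post_rates: RateConstants,
              fold_changes: dict[ControlPoint, float]) -> ControlSolution:
    adjusted = _adjust(post_rates, fold_changes)
    return ControlSolution(
        points=frozenset(fold_changes),
        fold_changes=dict(fold_changes),
        adjusted_rates=adjusted,
        achieved_ss=steady_state(adjusted),
        transition_time_tau=transition_time(adjusted, "protein"),
    )


def required_fold_change(
    point: ControlPoint,
    post_rates: RateConstants,
    target: SteadyState,
    species: str = "protein",
) -> ControlSolution:
    """Unique fold-change of one rate constant meeting a steady-state target.

    For F1, F3 and F4 the target species is the protein; F2 enters both
    steady states, so the caller states whether the mRNA or the protein
    level is to be restored (``species``).  Inverting the steady-state
    formulas gives the factor directly; a target requiring a non-positive
    rate raises ``ValueError``.
    """
    if species not in ("mrna", "protein"):
        raise ValueError("species must be 'mrna' or 'protein'")
    ss = steady_state(post_rates)
    if species == "mrna":
        if point not in (ControlPoint.F1, ControlPoint.F2):
            raise ValueError(
                f"{point.name} does not enter the mRNA steady state"
            )
        ratio = target.mrna_ss / ss.mrna_ss
    else:
        ratio = target.protein_ss / ss.protein_ss
    if not (math.isfinite(ratio) and ratio > 0):
        raise ValueError(f"target unattainable: required ratio {ratio}")
    # production rates scale the steady state up; degradation rates scale
    # it down, so their factor is the reciprocal
    factor = 1.0 / ratio if point.is_degradation else ratio
    return _solution(post_rates, {point: factor})


def mrna_side_effect(solution: ControlSolution,
                     pre_shift_ss: SteadyState) -> float:
    """mRNA steady state of the adjusted system over the pre-shift one.

    Transcription-only compensation (25-fold k1) pushes mRNA to 5x its
    pre-shift level — the hidden price of protein-level control at the
    mRNA tier.  Translation or protein-degradation control leaves mRNA at
    the (lower) uncompensated post-shift level instead.
    """
    return solution.achieved_ss.mrna_ss / pre_shift_ss.mrna_ss


def combined_control(
    points: set[ControlPoint] | frozenset[ControlPoint],
    post_rates: RateConstants,
    target: SteadyState,
    split: dict[ControlPoint, float] | None = None,
) -> ControlSolution:
    """Compensation distributed over several control points.

    The protein steady state is multiplied by each production factor and
    divided by each degradation factor, so the product of fold-change
    magnitudes must equal the total required compensation F (25 for the
    canonical cold shift).  ``split=None`` shares the burden equally:
    each of n points contributes F**(1/n) — e.g. fivefold each for
    {F1, F3} or {F2, F4}.  An explicit ``split`` maps each point to its
    rate-constant factor and is validated against F.
    """
    points = frozenset(points)
    if not points:
        raise ValueError("points must be non-empty")
    ss = steady_state(post_rates)
    total = target.protein_ss / ss.protein_ss
    if not (math.isfinite(total) and total > 0):
        raise ValueError(f"target unattainable: required total {total}")

    if split is None:
        share = total ** (1.0 / len(points))
        fold_changes = {
            p: (1.0 / share if p.is_degradation else share) for p in points
        }
    else:
        if frozenset(split) != points:
            raise ValueError("split must assign a factor to exactly the "
                             "requested points")
        achieved = 1.0
        for p, f in split.items():
            achieved *= (1.0 / f) if p.is_degradation else f
        if not math.isclose(achieved, total, rel_tol=_SPLIT_RTOL):
            raise ValueError(
                f"inconsistent split: effective product {achieved:g} != "
                f"required total {total:g}"
            )
        fold_changes = dict(split)
    return _solution(post_rates, fold_changes)


def transition_time(
    rates: RateConstants, level: str, method: str = "total_rate"
) -> float:
    """Transition time between steady states of the adjusted system.

    The primary formulas are ``tau_mRNA = 1/(k1 + k2)`` and
    ``tau_Protein = 1/(k1 + k2 + k3 + k4)``, implemented exactly as
    published even though k1 (zeroth order, concentration/time) is summed
    with first-order constants — they are the quantity the cost/speed
    front is defined on.  ``method='relaxation'`` gives the textbook
    relaxation times of the linear system instead (1/k2 for mRNA,
    1/min(k2, k4) for the protein cascade's slowest eigenvalue) as an
    independent cross-check.
    """
    if level not in ("mrna", "protein"):
        raise ValueError("level must be 'mrna' or 'protein'")
    if method == "total_rate":
        if level == "mrna":
            return 1.0 / (rates.k1 + rates.k2)
        return 1.0 / (rates.k1 + rates.k2 + rates.k3 + rates.k4)
    if method == "relaxation":
        if level == "mrna":
            return 1.0 / rates.k2
        return 1.0 / min(rates.k2, rates.k4)
    raise ValueError("method must be 'total_rate' or 'relaxation'")


def response_simulation(
    post_rates: RateConstants,
    solution: ControlSolution,
    mode: str,
    pre_shift_ss: SteadyState,
    duration: float = 40.0,
    n_points: int = 2001,
) -> Trajectory:
    """Simulate the compensated system from one of two starting points.

    ``mode='immediate'``: control is applied the moment the temperature
    drops, so the system starts at the pre-shift steady state.
    ``mode='settled'``: the system first relaxes into the uncompensated
    cold steady state, then control kicks in.  Either way the adjusted
    rates drive it to the restored steady state; the transient differs —
    immediate protein-side control (F3/F4) overshoots, immediate
    mRNA-side control (F1/F2) dips.
    """
    if mode == "immediate":
        init = pre_shift_ss.as_state()
    elif mode == "settled":
        init = steady_state(post_rates).as_state()
    else:
        raise ValueError("mode must be 'immediate' or 'settled'")
    return integrate_constant(solution.adjusted_rates, init, duration, n_points)


def pareto_front(
    post_rates: RateConstants,
    target: SteadyState,
    level: str,
    n_grid: int = 50,
) -> list[ParetoPoint]:
    """Cost-vs-speed front for paired production/degradation control.

    The production rate of the chosen tier (k1 for mRNA, k3 for protein)
    is up-regulated by ``u`` and the matching degradation rate
    down-regulated by ``d = F/u``, keeping the protein steady state on
    target for every grid point; ``u`` sweeps a log-spaced grid from 1
    (pure degradation control, slowest) to F (pure production control,
    fastest).  ``u`` proxies the ATP cost of the extra synthesis, so no
    point dominates another.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if level not in ("mrna", "protein"):
        raise ValueError("level must be 'mrna' or 'protein'")
    total = target.protein_ss / steady_state(post_rates).protein_ss
    if not (math.isfinite(total) and total > 1):
        raise ValueError(f"required total compensation must exceed 1, got {total}")
    up_point, down_point = (
        (ControlPoint.F1, ControlPoint.F2) if level == "mrna"
        else (ControlPoint.F3, ControlPoint.F4)
    )
    us = np.logspace(0.0, math.log10(total), n_grid)
    front = []
    for u in us:
        d = total / u
        adjusted = _adjust(post_rates, {up_point: u, down_point: 1.0 / d})
        front.append(ParetoPoint(
            up_factor=float(u),
            down_factor=float(d),
            tau=transition_time(adjusted, level),
        ))
    return front


def degradation_stop_response(
    post_rates: RateConstants,
    target: SteadyState,
    stop_duration: float,
    level: str = "protein",
    duration: float = 40.0,
    n_points: int = 2001,
) -> Trajectory:
    """Two-phase strategy: halt degradation briefly, then hold the target.

    Phase 1 sets the tier's degradation rate to zero for
    ``stop_duration`` starting from the settled cold steady state — a
    stronger, transient intervention that raises the level faster than
    the steady 25-fold reduction.  Phase 2 restores degradation at the
    exactly-compensating value so the trajectory settles on the target.
    Zero is outside the strictly-positive ``RateConstants`` domain, so
    phase 1 integrates the raw rate vector directly.
    """
    if level not in ("mrna", "protein"):
        raise ValueError("level must be 'mrna' or 'protein'")
    if not (0.0 < stop_duration < duration):
        raise ValueError("need 0 < stop_duration < duration")
    deg_point = ControlPoint.F2 if level == "mrna" else ControlPoint.F4
    hold = required_fold_change(deg_point, post_rates, target,
                                species=level)
    k = post_rates.as_array()
    idx = 1 if level == "mrna" else 3
    k_stopped = k.copy()
    k_stopped[idx] = 0.0

    def rhs_for(kv):
        def rhs(_t, y):
            return [kv[0] - kv[1] * y[0], kv[2] * y[0] - kv[3] * y[1]]
        return rhs

    init = steady_state(post_rates).as_state()
    ts = np.linspace(0.0, duration, n_points)
    mask = ts <= stop_duration
    sol1 = solve_ivp(rhs_for(k_stopped), (0.0, stop_duration),
                     [init.mrna, init.protein], method="DOP853",
                     t_eval=ts[mask], rtol=1e-8, atol=1e-10)
    end1 = solve_ivp(rhs_for(k_stopped), (0.0, stop_duration),
                     [init.mrna, init.protein], method="DOP853",
                     rtol=1e-8, atol=1e-10).y[:, -1]
    k_hold = hold.adjusted_rates.as_array()
    sol2 = solve_ivp(rhs_for(k_hold), (stop_duration, duration), end1,
                     method="DOP853", t_eval=ts[~mask], rtol=1e-8, atol=1e-10)
    if not (sol1.success and sol2.success):
        raise RuntimeError("ODE integration failed in degradation-stop protocol")
    ys = np.maximum(np.hstack([sol1.y, sol2.y]), 0.0)
    return Trajectory(ts, ys[0], ys[1])


def control_report(
    post_rates: RateConstants,
    target: SteadyState,
    pre_shift_ss: SteadyState,
) -> dict:
    """JSON-ready summary over all four single control points and the
    two canonical pairs: fold-changes, adjusted rates, achieved steady
    state, transition times (published formula and relaxation-time
    cross-check) and the mRNA side-effect ratio."""
    report: dict = {"single": {}, "combined": {}}
    for point in ControlPoint:
        sol = required_fold_change(point, post_rates, target)
        report["single"][point.name] = _solution_entry(sol, pre_shift_ss)
    for label, pts in (("F1+F3", {ControlPoint.F1, ControlPoint.F3}),
                       ("F2+F4", {ControlPoint.F2, ControlPoint.F4})):
        sol = combined_control(pts, post_rates, target)
        report["combined"][label] = _solution_entry(sol, pre_shift_ss)
    return report


def _solution_entry(sol: ControlSolution, pre_shift_ss: SteadyState) -> dict:
    return {
        "fold_changes": {p.name: f for p, f in sorted(
            sol.fold_changes.items(), key=lambda kv: kv[0].name)},
        "adjusted_rates": {k: getattr(sol.adjusted_rates, k)
                           for k in ("k1", "k2", "k3", "k4")},
        "achieved_steady_state": {
            "mrna": sol.achieved_ss.mrna_ss,
            "protein": sol.achieved_ss.protein_ss,
        },
        "tau_protein": sol.transition_time_tau,
        "tau_protein_relaxation": transition_time(
            sol.adjusted_rates, "protein", method="relaxation"),
        "mrna_side_effect": mrna_side_effect(sol, pre_shift_ss),
    }
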