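"""Synthetic western-blot time courses and parameter-recovery fitting.

Emulates the quantified immunoblot experiment behind the model: three
chloroplast proteins (PetA, PsbA, AtpA) sampled at 0, 0.5 min, 5 min,
20 min, 1 h, 5 h, 1 day and 2 days after a cold shift, in a control and
a shifted condition with three replicates each.  Band intensities are
normalized per replicate to the 0-min sample and averaged — so only
relative abundances survive, which matters for identifiability.

The latent signal is the kinetic model's protein trajectory (1 model
time unit = 1 hour), modulated by a slow shared sinusoid standing in for
circadian / developmental drift and multiplied by lognormal measurement
noise.  ``fit_rates`` closes the loop: a multi-start least-squares
recovery of the rate constants from (noisy) trajectories, flagging the
scale non-identifiability that normalization creates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import (
    RateConstants,
    ShiftProtocol,
    SystemState,
    Trajectory,
    _closed_form_arrays,
    steady_state,
)

__all__ = [
    "DEFAULT_TIME_POINTS_H",
    "BlotDesign",
    "NoiseModel",
    "BlotDataset",
    "generate_blots",
    "quantify_relative",
    "perturb_trajectory",
    "FitResult",
    "fit_rates",
]

#: sampling times after the shift, in hours
DEFAULT_TIME_POINTS_H = (0.0, 0.5 / 60, 5.0 / 60, 20.0 / 60, 1.0, 5.0, 24.0, 48.0)


@dataclass(frozen=True)
class BlotDesign:
    """Sampling design of the blot experiment."""

    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS_H
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("control", "shifted")
    proteins: tuple[str, ...] = ("PetA", "PsbA", "AtpA")

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        if not tp or tp[0] != 0.0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must start at 0 and strictly increase")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "time_points", tp)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise plus slow shared fluctuation.

    ``multiplicative_cv`` is the coefficient of variation of lognormal
    densitometry noise; the fluctuation is a sinusoid of fractional
    amplitude ``fluctuation_amplitude`` and period ``fluctuation_period``
    hours (default one day), identical in control and shifted series of
    a protein but phased independently per protein.
    """

    multiplicative_cv: float = 0.1
    fluctuation_amplitude: float = 0.15
    fluctuation_period: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0 or self.fluctuation_amplitude < 0:
            raise ValueError("cv and amplitude must be non-negative")
        if self.fluctuation_period <= 0:
            raise ValueError("fluctuation_period must be positive")


@dataclass(frozen=True)
class BlotDataset:
    """Tidy replicate-level relative abundances plus the averaged series.

    ``tidy`` has columns protein, condition, time_h, replicate,
    relative_abundance; ``averaged`` collapses replicates to their mean.
    Every averaged (and replicate-level) series equals 1 at time 0 by
    construction of the normalization.
    """

    tidy: pd.DataFrame
    design: BlotDesign
    noise: NoiseModel

    @property
    def averaged(self) -> pd.DataFrame:
        return (
            self.tidy.groupby(["protein", "condition", "time_h"], sort=True)
            ["relative_abundance"].mean().rename("mean_relative_abundance")
            .reset_index()
        )

    def series(self, protein: str, condition: str) -> np.ndarray:
        """Averaged relative series for one protein/condition, time-ordered."""
        df = self.averaged
        sel = df[(df["protein"] == protein) & (df["condition"] == condition)]
        return sel.sort_values("time_h")["mean_relative_abundance"].to_numpy()

    def to_tsv(self, tidy_path, averaged_path=None) -> None:
        self.tidy.to_csv(tidy_path, sep="\t", index=False)
        if averaged_path is not None:
            self.averaged.to_csv(averaged_path, sep="\t", index=False)


def _latent_protein(protocol: ShiftProtocol, condition: str,
                    times_h: np.ndarray) -> np.ndarray:
    """Model protein trajectory: both conditions start at the warm steady
    state; the shifted condition switches to the post rates at t = 0."""
    ss = steady_state(protocol.rates_pre)
    rates = protocol.rates_pre if condition == "control" else protocol.rates_post
    _, protein = _closed_form_arrays(rates, ss.mrna_ss, ss.protein_ss, times_h)
    return protein


def generate_blots(
    design: BlotDesign,
    protocol: ShiftProtocol,
    noise: NoiseModel,
) -> BlotDataset:
    """Simulate a quantified blot experiment; deterministic given the seed.

    Raw intensity = latent model protein x (1 + A sin(2 pi t / period +
    phase_protein)) x lognormal(cv) per measurement, then each replicate
    is normalized to its own 0-min sample as in the real quantification.
    """
    rng = np.random.default_rng(noise.seed)
    times = np.asarray(design.time_points)
    sigma = math.sqrt(math.log1p(noise.multiplicative_cv ** 2))
    rows = []
    for protein_label in design.proteins:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        fluct = 1.0 + noise.fluctuation_amplitude * np.sin(
            2.0 * math.pi * times / noise.fluctuation_period + phase
        )
        for condition in design.conditions:
            latent = _latent_protein(protocol, condition, times) * fluct
            for rep in range(1, design.n_replicates + 1):
                if sigma > 0:
                    lognoise = rng.lognormal(-0.5 * sigma ** 2, sigma,
                                             size=times.size)
                else:
                    lognoise = np.ones_like(times)
                raw = latent * lognoise
                rel = raw / raw[0]
                rows.extend(
                    {
                        "protein": protein_label,
                        "condition": condition,
                        "time_h": float(t),
                        "replicate": rep,
                        "relative_abundance": float(v),
                    }
                    for t, v in zip(times, rel)
                )
    return BlotDataset(tidy=pd.DataFrame(rows), design=design, noise=noise)


def quantify_relative(raw: np.ndarray) -> np.ndarray:
    """Blot quantification: per-replicate 0-min normalization, then mean.

    ``raw`` is (n_replicates, n_time_points) of band intensities; each
    replicate is divided by its own first (0-min) value and the
    replicates averaged per time point.  Invariant to rescaling any
    single replicate.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    t0 = raw[:, 0]
    if np.any(t0 <= 0) or not np.all(np.isfinite(t0)):
        raise ValueError("0-min intensity must be positive in every replicate")
    return (raw / t0[:, None]).mean(axis=0)


def perturb_trajectory(traj: Trajectory, cv: float, seed: int) -> Trajectory:
    """Multiply both series by lognormal noise of the given CV (mean 1)."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return traj
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv ** 2))
    noisy = [
        series * rng.lognormal(-0.5 * sigma ** 2, sigma, size=series.size)
        for series in (traj.mrna, traj.protein)
    ]
    return Trajectory(traj.times, noisy[0], noisy[1])


@dataclass(frozen=True)
class FitResult:
    """Outcome of a rate-constant fit."""

    rates: RateConstants
    rss: float
    converged: bool
    fixed: dict[str, float]
    warnings: tuple[str, ...] = ()
    n_starts: int = 1


_RATE_NAMES = ("k1", "k2", "k3", "k4")
_DEFAULT_BOUNDS = {name: (1e-3, 1e2) for name in _RATE_NAMES}


def _trajectory_residuals(params_full: np.ndarray, traj: Trajectory
                          ) -> np.ndarray:
    rates = RateConstants(*params_full)
    dt = traj.times - traj.times[0]
    m0, p0 = traj.mrna[0], traj.protein[0]
    m, p = _closed_form_arrays(rates, m0, p0, dt)
    return np.concatenate([m - traj.mrna, p - traj.protein])


def _relative_residuals(params_full: np.ndarray, dataset: BlotDataset
                        ) -> np.ndarray:
    # Dividing mRNA by its pre-shift steady state and protein by its own
    # maps the model onto itself with effective rates (k1/mRNA_ss_pre,
    # k2, k3*mRNA_ss_pre/Protein_ss_pre, k4) and initial state (1, 1);
    # the fitted parameters are those effective rates, not absolute ones.
    rates = RateConstants(*params_full)
    times = np.asarray(dataset.design.time_points)
    _, model_rel = _closed_form_arrays(rates, 1.0, 1.0, times)
    res = [
        dataset.series(protein_label, "shifted") - model_rel
        for protein_label in dataset.design.proteins
    ]
    return np.concatenate(res)


def fit_rates(
    data: Trajectory | BlotDataset,
    known: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 5,
) -> FitResult:
    """Least-squares recovery of rate constants from a time course.

    A deterministic local optimizer (trust-region reflective) is run
    from ``n_starts`` starting points drawn log-uniformly from the
    bounds with the given seed; the best solution is kept.  Rates in
    ``known`` are held fixed.  Fitting a normalized ``BlotDataset``
    cannot recover absolute scale — the returned values are then the
    effective scale-free rates of the normalized system, and the result
    carries a 'scale-non-identifiable' warning.
    Non-convergence of every start is reported via ``converged=False``,
    never as an exception.
    """
    known = dict(known or {})
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    warnings: list[str] = []

    if isinstance(data, BlotDataset):
        warnings.append(
            "scale-non-identifiable: data are 0-min-normalized, so the "
            "fitted values are effective scale-free rates (k1/mRNA_ss_pre, "
            "k2, k3*mRNA_ss_pre/Protein_ss_pre, k4); absolute k1 is not "
            "identifiable from relative abundances"
        )
        residual = lambda p: _relative_residuals(p, data)
        n_obs = len(data.design.time_points) * len(data.design.proteins)
    else:
        residual = lambda p: _trajectory_residuals(p, data)
        n_obs = 2 * data.times.size

    free = [n for n in _RATE_NAMES if n not in known]
    if not free:
        raise ValueError("no free parameters to fit")
    if n_obs < len(free):
        raise ValueError("fewer data points than free parameters")

    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])

    def assemble(theta: np.ndarray) -> np.ndarray:
        full = []
        it = iter(theta)
        for n in _RATE_NAMES:
            full.append(known[n] if n in known else next(it))
        return np.array(full)

    rng = np.random.default_rng(seed)
    starts = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=(n_starts, len(free)))
    )
    best = None
    any_converged = False
    for x0 in starts:
        try:
            sol = least_squares(
                lambda th: residual(assemble(th)), x0, bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        any_converged = any_converged or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))
    if best is None:
        raise RuntimeError("all optimizer starts failed to evaluate")
    rss, theta, _ = best
    return FitResult(
        rates=RateConstants(*assemble(theta)),
        rss=rss,
        converged=any_converged,
        fixed=known,
        warnings=tuple(warnings),
        n_starts=n_starts,
    )
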