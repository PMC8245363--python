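# Methods

## Model

The package models a single chloroplast gene as a linear two-stage
cascade: constitutive transcription at rate `k1` (concentration/time),
first-order mRNA decay (`k2`), translation proportional to mRNA (`k3`)
and first-order protein decay (`k4`), all in arbitrary units. The
assumptions are deliberately minimal: no polymerase/ribosome species, no
saturation, no feedback, no stochasticity, instantaneous temperature
shifts (piecewise-constant rates). Under these assumptions the system
is globally stable with steady states `mRNA_ss = k1/k2`,
`Protein_ss = k1·k3/(k2·k4)`, and admits an exact two-exponential
solution; when `k2 = k4` (detected at relative tolerance 1e-12) the
driven term degenerates to the `t·exp(−k·t)` limit form, which is
implemented explicitly.

Simulations start by default from the empty state (no mRNA, no protein)
and, in the canonical shift protocol, switch rates at `t = 400` of a
1200-unit window; both are configurable. The numerical integrator is
scipy's adaptive explicit DOP853 at `rtol 1e-8`, `atol 1e-10` — the
system is linear and non-stiff, so an explicit method is cheap and the
closed-form solution serves as an independent oracle (the test suite
requires 1e-6 relative agreement on random rate sets).

## Temperature scaling

Arrhenius (`k = A·exp(−ΔG/RT)`) and Stokes–Einstein
(`D = k_B·T/(6πηR₀)`) relations are provided as utilities with CODATA
constants, but activation energies for composite processes like
transcription are not tabulated, so the cold-shift scenarios are driven
by per-reaction multiplicative factors instead. The physical argument
connecting them is the encounter count: synthesizing an mRNA for a
typical 350-aa protein needs ~3×350 ≈ 10³ successful diffusive
encounters and translation ~350, whereas a protease or RNase needs one
— hence production rates fall much more steeply on cooling. Physics
functions take absolute temperature in Kelvin (`celsius_to_kelvin` is
provided); the CLI and configs speak °C where a temperature appears.

Two slowdown conventions coexist in the literature the rate tables draw
on: a factor of 10 per 10 °C for production (used by the packaged cold
rate set) and a Q10 of ~2.5 derived from translation measurements
(available via `q10_factor`). They are not reconciled here; both are
exposed and the choice is the user's. The uniform-slowdown scenario
(`fig3a`) uses factor 0.1 on all four rates so that its production rates
match the other scenarios, which preserves the key invariance result
(uniform scaling leaves both steady states untouched — scale invariance
is a property test). Viscosity's own temperature dependence is not
modeled; η is a user input to the diffusion formula.

## Control-point analysis

Because the steady states are monomials in the rates, the fold-change
any single control point needs is an exact inversion, not a numeric
search: with the packaged rate sets, 25-fold up for k1 or k3, 25-fold
down for k2 or k4 to restore the protein level, and 5-fold down for k2
to restore mRNA alone. Joint control distributes the burden as a
product constraint (equal split over n points gives `25^(1/n)` each);
an explicit split is validated against the required total at relative
tolerance 1e-9. Fold-changes are defined on rate constants (25-fold
decrease means `k → k/25`).

Transition times use the published formulas `τ_mRNA = 1/(k1+k2)` and
`τ_Protein = 1/(k1+k2+k3+k4)` verbatim, although `k1` is a zeroth-order
constant with different units from the first-order terms; this
dimensional wrinkle is inherited deliberately, since the cost/speed
front is defined on these τ values. The textbook relaxation times
(`1/k2`; slowest eigenvalue `1/min(k2,k4)`) are available via
`method="relaxation"` as a clearly separated cross-check, and both
appear in the JSON control report.

Response simulations distinguish an immediate reaction (start at the
warm steady state, adjusted rates from t = 0) from a settled one (start
at the cold uncompensated steady state). The transient direction is a
structural property asserted in tests: protein-side control (F3/F4)
overshoots, mRNA-side control (F1/F2) dips, because the mRNA pool lags
the protein target. The Pareto front sweeps the production up-factor u
over a log-spaced grid (default 50 points) from 1 to the required total
F, with the paired degradation factor `F/u`; τ is strictly decreasing in
u, so every grid point is Pareto-optimal. The transient
"stop degradation entirely, then hold" strategy is implemented as a
two-phase integration over raw rate vectors, since a zero rate is
outside the strictly positive `RateConstants` domain.

## Synthetic blot data

The generator emulates a quantified immunoblot time course: three
proteins, control and shifted conditions, three replicates, sampled at
0, 0.5 min, 5 min, 20 min, 1 h, 5 h, 1 day and 2 days. One model time
unit is mapped to one hour (fixed but configurable; nothing in the
kinetics pins the a.u. to wall-clock time). Both conditions start at
the warm steady state; the shifted condition switches to the cold rates
at t = 0. The latent protein signal is multiplied by

- a slow sinusoid (default amplitude 0.15, period 24 h, one random
  phase per protein, shared between conditions) standing in for
  circadian/developmental drift seen in real time courses, and
- mean-one lognormal measurement noise (default CV 0.1, a realistic
  densitometry figure; no noise model is published for the data being
  emulated, so this is the package's own choice).

Each replicate is then normalized to its own 0-min sample and replicates
are averaged — the same quantification as the wet-lab protocol. What the
generator does *not* emulate: image-level artifacts, loading-control
normalization, blot saturation, or biological replicate structure beyond
i.i.d. noise. Tests passing on these data therefore validate the
analysis pipeline's logic, not the realism of any particular wet-lab
dataset.

## Parameter fitting

`fit_rates` minimizes squared residuals of the closed-form solution
against an observed time course, using scipy's trust-region-reflective
`least_squares` under positivity bounds (default `[1e-3, 1e2]` per
rate), with 5 starting points drawn log-uniformly from the bounds by a
caller-supplied seed to guard against local minima; the best start wins
and total non-convergence is reported as a flag, never an exception.
Fitting absolute trajectories identifies all four rates (noiseless
recovery is exact to optimizer precision; at 5% noise the degradation
rates come back with <10% median error over seeds, both asserted in the
test suite). Normalized blot data are scale-free: dividing mRNA and
protein by their warm steady states maps the model onto itself with
effective rates `(k1/mRNA_ss, k2, k3·mRNA_ss/Protein_ss, k4)` and
initial state (1, 1), so the fit operates in that coordinate system and
attaches a `scale-non-identifiable` warning rather than pretending to
recover absolute `k1`.

## Problem sizes and numerical choices

Default trajectory grids are 601 points (2001 for response transients);
the oracle-agreement property uses 100 random rate sets on a 31-point
grid; noisy-recovery statistics use 20 seeds with 3 optimizer starts
each; the Monte-Carlo null check of the blot generator uses 100 seeds of
a single-protein design. These sizes make every analysis a sub-second to
few-second computation while keeping the statistical assertions
well-powered. Steadiness detection (`is_steady`) declares a trajectory
settled when the spread over the final 10% of the time window is below a
relative tolerance (default 1e-4) for both species.

## Known limitations

- Single gene, no resource coupling: up-regulating translation 25-fold
  in the model costs nothing except the reported ATP proxy; in a real
  chloroplast ribosomes are shared and cold-limited.
- The τ formulas are heuristic (see above); eigenvalue-based relaxation
  times can differ by large factors for strongly asymmetric rate sets.
- The instantaneous-shift assumption ignores the minutes-scale thermal
  equilibration of real tissue.
- Relative blot data cannot constrain absolute synthesis rates; any
  fit quality on such data concerns shape only.
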