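"""How much must each rate change to restore the warm protein level?

With the cold rate set, inverting the steady-state formulas shows any
single control point must move 25-fold: transcription or translation up,
or either degradation down.  Transcription-only control drags mRNA to
five times its warm level as a side effect; splitting the burden over
two points needs only fivefold each.
"""

from coldshift import (
    ControlPoint, RATES_14C, RATES_24C, combined_control, mrna_side_effect,
    required_fold_change, steady_state, transition_time,
)

warm = steady_state(RATES_24C)

for point in ControlPoint:
    sol = required_fold_change(point, RATES_14C, warm)
    f = sol.fold_changes[point]
    direction = f"x {f:.0f}" if f >= 1 else f"/ {1 / f:.0f}"
    print(f"{point.name} ({point.value:<19s}): rate {direction}"
          f"  -> protein {sol.achieved_ss.protein_ss:.2f}, "
          f"mRNA side effect {mrna_side_effect(sol, warm):.1f}x, "
          f"tau {sol.transition_time_tau:.3f}")

pair = combined_control({ControlPoint.F1, ControlPoint.F3}, RATES_14C, warm)
print(f"\nF1+F3 jointly: {pair.fold_changes[ControlPoint.F1]:.0f}-fold each "
      f"(product 25), tau {pair.transition_time_tau:.3f}")
print("tau is the transition time 1/(k1+k2+k3+k4) of the adjusted system; "
      "textbook relaxation time for comparison:",
      f"{transition_time(pair.adjusted_rates, 'protein', 'relaxation'):.3f}")
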