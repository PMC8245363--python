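"""Cost versus speed of compensation: the Pareto front.

Pairing production up-regulation (factor u, an ATP-cost proxy) with
degradation down-regulation (factor 25/u) always restores the protein
steady state, but the transition time shrinks as u grows — paying more
synthesis always buys speed, so no strategy dominates another.
"""

from coldshift import RATES_14C, RATES_24C, pareto_front, steady_state

warm = steady_state(RATES_24C)
front = pareto_front(RATES_14C, warm, level="mrna", n_grid=7)

print("up_factor  down_factor  tau")
for p in front:
    print(f"{p.up_factor:9.2f}  {p.down_factor:11.2f}  {p.tau:.4f}")
print(f"\npure degradation control (u=1) is "
      f"{front[0].tau / front[-1].tau:.0f}x slower than pure "
      "transcription control (u=25), but costs no extra synthesis")
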