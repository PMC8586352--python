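"""Translate an observed screen LFC into growth-rate terms.

A +2.5 LFC over a 21-day screen looks dramatic, but corresponds to a modest
~12% increase in growth rate — and the same rate change would produce only
~1.7 LFC in a 14-day screen, inside the noise band of null knockouts.  This
is why positive-selection phenotypes need long assays.
"""

from psgkit import growth

scenario = growth.GrowthScenario.from_lfc(lfc=2.5, t=21, k_wt=1.0)

print(f"observed LFC:            {scenario.lfc} over {scenario.t:.0f} days")
print(f"growth-rate change:      {scenario.delta_k:.2f} doublings/day")
print(f"fitness increase:        {scenario.fitness_increase_percent:.0f}%")
print(f"doubling time:           {scenario.doubling_time_wt_hours:.0f} h -> "
      f"{scenario.doubling_time_ko_hours:.0f} h")
print(f"projected LFC at 14 d:   "
      f"{growth.lfc_from_delta_k(scenario.delta_k, 14):.1f}")
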