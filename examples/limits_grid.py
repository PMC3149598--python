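"""How many clusters buy how much: MAP and MDD over a (k, ICC) grid.

Evaluates the limiting quantities for a standardised effect of 0.2 and
prints a small pivot: maximum achievable power by clusters-per-arm and
ICC.  Values of 1.0 (ICC = 0) mean power is unbounded; everything else
is the ceiling no cluster size can beat.
"""
from crctdesign import GridSpec, TestParams, compute_grid

test = TestParams(alpha=0.05, power=0.80)
grid = compute_grid(GridSpec(quantity="map_continuous",
                             rho_values=(0.0, 0.02, 0.05, 0.1),
                             effect_values=(0.2,)), test)
print(grid.pivot(index="k", columns="rho", values="value").round(3))

mdd = compute_grid(GridSpec(quantity="mdd_continuous",
                            rho_values=(0.02, 0.05, 0.1)), test)
print()
print("Minimum detectable standardised effect at 80% power:")
print(mdd.pivot(index="k", columns="rho", values="value").round(3))
# Each MDD cell is the smallest standardised effect detectable at 80%
# power however large the clusters are made.
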