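"""Behavioral predictions as the switch cost changes, foveal and peripheral.

Foveal task (beta = 0.68, c = 0.005): raising the switch cost from 0 to 0.1
makes the cost-sensitive policy switch far less, while Infomax (whose policy
ignores costs entirely) is unaffected and ends up paying much more.
Peripheral task (tiers 0.62/0.60/0.55/0.50, c = 0.05, start at the center):
the same adaptation appears between cs = 0 and cs = 0.005.
"""

import numpy as np

import cdac
from cdac.inference import GridDynamics

grid = cdac.build_belief_grid(3, 200)
uni = np.ones(3) / 3

model = cdac.ObservationModel(3, 0.68)
dyn = GridDynamics(grid, model)
c0, c1 = cdac.CostParams(0.005, 0.0), cdac.CostParams(0.005, 0.1)
_, p0 = cdac.solve_cdac(model, c0, grid, declare_rule="current", dynamics=dyn)
_, p1 = cdac.solve_cdac(model, c1, grid, declare_rule="current", dynamics=dyn)
_, pi = cdac.solve_infomax(model, grid, cdac.theorem1_threshold(0.68, 0.005), dynamics=dyn)

stats = cdac.compare_policies(
    {"C-DAC cs=0": (p0, model, c0), "C-DAC cs=0.1": (p1, model, c1),
     "Infomax cs=0": (pi, model, c0), "Infomax cs=0.1": (pi, model, c1)},
    uni, uni, 10_000, seed=11, initial_fixation="uniform",
)
print("Foveal task (10,000 paired trials):")
for name, s in stats.items():
    print(f"  {name:14s} acc {s.accuracy:.3f}  steps {s.mean_steps:5.2f}  "
          f"switches {s.mean_switches:5.3f}  total cost {s.mean_cost:.3f}")

peri = cdac.PeripheralModel((0.62, 0.60, 0.55, 0.50))
dynp = GridDynamics(grid, peri)
print("\nPeripheral task (start at center, 10,000 trials):")
for cs in (0.0, 0.005):
    costs = cdac.CostParams(0.05, cs)
    _, pol = cdac.solve_cdac(peri, costs, grid, dynamics=dynp)
    trials = cdac.run_experiment(pol, peri, costs, uni, 10_000, uni, seed=13,
                                 initial_fixation=6)
    s = cdac.summarize(trials, costs)
    print(f"  C-DAC cs={cs:<6} acc {s.accuracy:.3f}  steps {s.mean_steps:5.2f}  "
          f"switches {s.mean_switches:5.3f}")
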