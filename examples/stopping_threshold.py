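"""Closed-form stopping threshold and its inner-bound property.

Computes the confidence level p* above which stopping and declaring is
provably optimal (zero switch cost), then verifies on a solved policy that
every grid belief exceeding p* is indeed a stopping state.
"""

import cdac

for beta, c in [(0.9, 0.1), (0.68, 0.005)]:
    p_star = cdac.theorem1_threshold(beta, c)
    print(f"beta={beta}, c={c}:  p* = {p_star:.4f}")

beta, c = 0.9, 0.1
grid = cdac.build_belief_grid(3, 200)
model = cdac.ObservationModel(3, beta)
_, policy = cdac.solve_cdac(model, cdac.CostParams(c, 0.0), grid)
p_star = cdac.theorem1_threshold(beta, c)
above = (grid.points > p_star).any(axis=1)
region = cdac.stopping_region(policy, fixation=0)
print(f"\ngrid points above p*: {int(above.sum())}, "
      f"all inside the solved stopping region: {bool(not (above & ~region).any())}")
print(f"solved stopping region is larger: {int(region.sum())} points "
      "(the bound is an inner bound, not the exact boundary)")
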