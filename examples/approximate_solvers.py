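"""Low-dimensional surrogates for the exact value function.

Fits the radial-basis-function and Gaussian-process surrogates at
(c, cs, beta) = (0.1, 0.1, 0.9) and reports how many outer sweeps each
needs and how closely the induced grid policy matches the exact solver
(fraction of identical actions over all 20301 x 3 belief-fixation pairs).
"""

import numpy as np

import cdac

grid = cdac.build_belief_grid(3, 200)
model = cdac.ObservationModel(3, 0.9)
costs = cdac.CostParams(0.1, 0.1)
V_exact, pol_exact = cdac.solve_cdac(model, costs, grid)

vf, pol, sweeps = cdac.solve_cdac_rbf(
    model, costs, cdac.RBFConfig(M=49, sigma2=0.05, m=200, seed=0), grid
)
print(f"RBF (49 bases):  {sweeps} sweeps, policy agreement "
      f"{cdac.policy_agreement(pol, pol_exact):.3f}, "
      f"mean |V - V_exact| = {np.abs(vf.values - V_exact.values).mean():.4f}")

for ard in (False, True):
    cfg = cdac.GPRConfig(n_points=200, length_scale=1.0, signal_variance=1.0,
                         noise_variance=0.1, ard=ard, seed=0)
    vg, pg, sg = cdac.solve_cdac_gpr(model, costs, cfg, grid)
    label = "GPR + ARD     " if ard else "GPR (fixed)   "
    print(f"{label}:  {sg} sweeps, policy agreement "
          f"{cdac.policy_agreement(pg, pol_exact):.3f}, "
          f"mean |V - V_exact| = {np.abs(vg.values - V_exact.values).mean():.4f}")
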