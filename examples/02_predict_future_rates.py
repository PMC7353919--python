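"""Fit one gene and predict its rates and expression beyond the measured
window — the pulse model extrapolates toward the new steady state.

Run:  python examples/02_predict_future_rates.py   (a few seconds)
"""

import numpy as np

import rnapulse as rp
from rnapulse.estimate import GeneData

cfg = rp.SimConfig(n_genes=5, seed=7, noise_cv=0.02)
expr, truth = rp.make_dataset(cfg)
g = expr.genes[0]
gd = GeneData(*expr.gene_arrays(g), grid=expr.grid)
kin = rp.fit_gene(gd, truth.scale_factors, rp.FitConfig(n_restarts=5, seed=3))

print(f"{g}: fitted objective J = {kin.J:.3f}")
initial, final = rp.steady_state_rates(kin)
print(f"initial steady-state rates (alpha,gamma,beta): "
      f"({initial[0]:.3f}, {initial[1]:.3f}, {initial[2]:.3f}) expr/min")
print(f"predicted new steady state:                    "
      f"({final[0]:.3f}, {final[1]:.3f}, {final[2]:.3f}) expr/min")

# measured window ends at 180 min; predict beyond it
for t in (180.0, 240.0, 360.0):
    a = rp.pulse_eval(kin.theta_alpha, t)
    T = rp.predict_total(kin, t)
    rc = rp.convert_rates(kin, t)
    print(f"t = {t:5.0f} min: alpha = {a:.3f} expr/min, total RNA = {T:.3f}, "
          f"degradation constant = {rc.beta_k:.3f} /min")
# the rates converge to the h2 levels (the new steady state) and the
# expression prediction flattens accordingly.
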