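"""Simulate a small 4sU time course, fit the pulse model, and score how
well the true kinetic rate curves are recovered.

Run:  python examples/01_simulate_and_fit.py   (~1 minute)
"""

import rnapulse as rp

# 30 genes, 13 samples 0-180 min, 10-min 4sU pulse, 10% multiplicative noise
cfg = rp.SimConfig(n_genes=30, seed=42)
expr, truth = rp.make_dataset(cfg)
print(f"simulated {expr.n_genes} genes x {expr.grid.n} time points "
      f"(tL = {expr.grid.tL} min)")

fit_cfg = rp.FitConfig(n_restarts=10, seed=1)
fits = rp.fit_all(expr, fit_cfg)
sf = fits.scale_factors
print(f"estimated scale factors: c1 = {sf.c1:.3f} (embedded {cfg.c1}), "
      f"c2 = {sf.c2:.3f} (embedded {cfg.c2})")

metrics = rp.evaluate_recovery(fits, truth)
print(metrics.round(3))
# pcc: Pearson correlation between fitted and true log10 rates, pooled
# over genes and time points, per rate class; mse on the same scale.
# Transcription and processing are typically recovered with PCC > 0.9
# at this size; degradation is the hardest because the total RNA pool
# moves slowly relative to its turnover.
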