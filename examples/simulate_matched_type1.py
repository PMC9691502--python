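"""Simulate the matched non-bursting (Type I) model and check its SCCs.

Builds the published matched configuration — exponential dynamic threshold
(v = 1.845 V, A = 0.15 V, tau = 30 ms), spikes locked to an EOD grid of
1.06 ms, slow AR(1) threshold noise (a = 0.4, R0 = 1.07e-3 V^2) — simulates
2e5 intervals, and compares the estimated serial correlation coefficients
with the linearized closed form rho_k = -a^(k-1)(1-a)/2.
"""

import numpy as np

from dynthresh import (ARNoiseSpec, EODGrid, ModelParams, SCCEstimatorConfig,
                       estimate_sccs, scc_type1, simulate_isis)

params = ModelParams(v=1.845, A=0.15, tau=30.0)  # gamma defaults to A/2
spec = ARNoiseSpec(a=0.4, sign=+1, r0=1.07e-3)
grid = EODGrid(period=1.06)

isis = simulate_isis(params, spec, n_isis=200_000, seed=1, grid=grid)
est = estimate_sccs(isis, SCCEstimatorConfig(block_size=2000, max_lag=15))
closed = scc_type1(0.4, K=15)

print(f"mean ISI: {isis.mean * 1.06:.3f} ms ({isis.mean:.2f} EOD cycles), "
      f"CV = {isis.cv:.3f}")
print("lag   rho (simulated)   rho (linearized closed form)")
for k in range(1, 6):
    print(f"{k:3d}   {est.rho[k]:+.4f} +- {est.se[k]:.4f}      {closed.rho[k]:+.4f}")
print(f"sum over 15 lags: {est.rho[1:].sum():+.4f}  (theory: -0.5)")
print()
print("The simulated rho_1 is more negative than the linearized -0.30 because")
print("EOD-grid quantization adds a differenced timing perturbation; the sum")
print("rule sum_k rho_k = -1/2 survives quantization.")
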