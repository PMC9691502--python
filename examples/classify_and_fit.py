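"""Analyze a synthetic spike train end to end and refit its parameters.

Generates the strongly bursting fixture (Type II pattern, bimodal ISI
distribution with a burst mode near one EOD cycle), estimates its SCCs,
classifies the pattern, and recovers the AR noise magnitude from the lag
ratio rho_2/rho_1.
"""

from dynthresh import (classify_pattern, estimate_sccs, fit_noise,
                       generate_fixtures, isi_distributions)

bundle = generate_fixtures("type2_strong", n_spikes=150_000, seed=3)
true_a = bundle.manifest["noise"]["a"]

est = estimate_sccs(bundle.isis)
pattern = classify_pattern(est)
hist = isi_distributions(bundle.isis, bin_width=1.0)
spec = fit_noise(est, v=1.845, snr_db=27.0)

print(f"pattern: {pattern.value}   (rho_1 = {est.rho[1]:+.3f}, "
      f"rho_2 = {est.rho[2]:+.3f})")
print(f"ISI modes: {hist.n_modes} at {hist.mode_positions} EOD cycles "
      f"-> {'bursting (bimodal)' if hist.bimodal else 'non-bursting'}")
print(f"recovered noise magnitude a = {spec.a:.3f} "
      f"(generator used a = {true_a}, negative coefficient)")
print()
print("A burst mode at ~1 EOD cycle plus alternating damped SCCs is the")
print("signature of fast (high-pass) threshold noise.")
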