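# Methods

## Model and assumptions

The encoder is deliberately minimal: a constant bias `v` (no membrane
integration, no voltage reset, no refractory period, no conductances), a
spike generator emitting Dirac impulses, and a non-resetting dynamic
threshold `r(t)` that jumps by `A` at each spike and relaxes exponentially
with time constant `τ`. A spike fires when the coding error `e(t) = v − r(t)`
reaches the spike threshold. Memory lives entirely in `r(t)`, which is the
spike train convolved with `A·exp(−t/τ)`. Stochasticity enters in exactly
one place: the spike threshold takes a random value `γᵢ = γ + gᵢ` drawn
immediately after spike `i−1` and held until spike `i`, with `gᵢ` a
zero-mean discrete wide-sense-stationary sequence. An equivalent
formulation perturbs the relaxation time constant instead
(`A·τᵢ = τ(gᵢ − gᵢ₋₁ + A)`); under the linearized rule the two produce
identical spike times, and the package exposes the transformation
(`tau_sequence_from_threshold_noise`).

Two firing rules are implemented.

* **Linearized** (`simulate_linearized`): the exponential decay is replaced
  by its tangent of slope `−m`, `m = (v − γ + A)/τ`, giving
  `ISIᵢ = (gᵢ − gᵢ₋₁ + A)/m` exactly. This is the regime in which the
  closed-form SCC theory is exact; it is valid at high rates
  (`T₁/τ ≪ 1`) and for noise excursions small against `A`. A nonpositive
  interval is a hard `DomainError` (never clipped), so the linearization's
  validity is never silently violated.
* **Exponential** (`simulate_exponential`): event-driven with the exact
  per-interval crossing `ISIᵢ = τ·ln[(v − γᵢ₋₁ + A)/(v − γᵢ)]` — no time
  stepping, so no `dt` enters as a tolerance. With an EOD grid enabled the
  spike is emitted at the first grid point at or after the continuous
  crossing, never in the cycle of the previous spike (at most one spike per
  EOD cycle), and the jump `A` is applied to the barrier value at the
  actual emission time.

Initial condition: `t₀ = 0` with the barrier at its post-spike value; the
first 100 intervals of every pipeline run are discarded as burn-in
(`DEFAULT_BURN_IN`). Internal time is milliseconds; grid-locked trains are
also expressible in integer EOD cycles (the unit tag on `ISISequence` is
mandatory).

## Threshold-noise processes

AR(1) noise `g_k = ±a·g_{k−1} + w_k` is the discrete sampling, at the mean
ISI, of an Ornstein–Uhlenbeck relaxation with `a = exp(−T₁/τ_γ)`. The
innovations are Gaussian — the distribution is a design choice, made for
the OU correspondence — and the first sample is drawn from the stationary
distribution `N(0, R₀)` so the sequence is stationary from sample 1. Power
is specified either as `R₀` (V²) or through the SNR convention
`SNR = 10·log₁₀(v²/R₀)`.

`generate_from_acf` samples a stationary Gaussian sequence whose population
autocorrelation equals an arbitrary prescribed `R₀..R_K` — the plumbing that
lets one simulate from the inverse solver's output. The construction is the
maximum-entropy (autoregressive) completion of the ACF: the Yule–Walker
system on the Toeplitz covariance yields AR(K) coefficients whose
stationary process matches the prescribed ACF exactly at lags `0..K` and
decays beyond; the first `K` samples come from a Cholesky factor of the
Toeplitz head and the rest from the O(n) recursion. Indefinite input
(smallest Toeplitz eigenvalue below `−10⁻⁸·R₀`) is rejected; near-singular
input is regularized with a diagonal jitter recorded in the output
metadata.

## Forward and inverse maps

The forward map `ρ_k = −(R_{k−1} − 2R_k + R_{k+1})/(2(R₀ − R₁))` is a
normalized second difference: it is scale invariant, independent of
`(v, γ, A, τ)`, and telescopes so that `Σ_{k=1}^{K} ρ_k =
−(R₀ − R₁ − R_K + R_{K+1})/(2(R₀ − R₁)) → −1/2` whenever the noise
decorrelates. The separability identity
`ρ₁ = −1/2 + (R₁ − R₂)/(2(R₀ − R₁))` splits the differencing (moving-
average) contribution `−1/2` from the noise-memory contribution.

The inverse problem is a two-point boundary-value problem for the second-
difference recurrence `R_{k+1} = 2R_k − R_{k−1} − D·ρ_k`, `D = 2(R₀ − R₁)`.
The package closes it with `R₀ = 1` and `R_{K+1} = 0`; summing the
recurrence twice (the discrete Green's function) gives
`R₁ = (K + 2S)/(K + 1 + 2S)` with `S = Σ_{j=1}^{K}(K+1−j)ρ_j`, after which
the recurrence fills in the remaining lags. This boundary closure is one
defensible choice among several — the inverse is only determined up to the
assumed tail behavior of `R`. Continuing one step with `ρ_{K+1} = 0` gives
the diagnostic residual `|R_{K+2}| = |R_K|`, which vanishes exactly when
the supplied partial SCC sum equals `−1/2`; an inconsistent prescription
shows up entirely in this residual (no separate least-squares branch is
needed, since the boundary problem always has the closed-form solution). A
solution violating `|R_k| ≤ R₀` is flagged non-physical with a warning.
Round-trip accuracy on AR(1) ACFs (both signs, `a ≤ 0.69`, `K = 50`) is at
the `10⁻⁸` level, limited by the truncated tail `a^{K+1}`.

## Estimators

The blockwise SCC estimator follows the reference estimator verbatim:
deviations about the **global** mean `T₁`, per-block sums over
non-overlapping blocks of `M` intervals (default 2000, sensible range
1000–3000), normalization by the product of the two per-block root sums,
block values averaged and the between-block scatter reported as
`s.e. = s.d./√n_blocks`. `ρ̂₀ = 1` by construction. Blocks with zero
variance and runs with fewer than one block are hard errors.

Partial autocorrelations use the Durbin recursion with `φ₁,₁ = ρ₁` exactly
and the denominators `1 − Σφ_{k,j}ρ_j` retained for audit; a brute-force
Yule–Walker solve at each order serves as the in-test oracle (agreement to
`10⁻¹⁰` at `K = 15`), with statsmodels' Levinson–Durbin as an independent
cross-check.

The DC-power check bins the train at the EOD period (grid base) or `T₁/4`
(continuous), takes the mean-subtracted periodogram, converts to the
point-process power density in the angular-frequency convention
(`P(ω) = Pxx/(4πΔ²)` for a one-sided count-series density `Pxx`), and
averages the lowest 2% of frequencies excluding the DC bin. The analytic
comparison is `P(0) = C²/(2πT₁)(1 + 2Σρ̂)`; a shuffled (renewal) surrogate
reproduces the `C²/(2πT₁)` level within Monte-Carlo error, and the
white-threshold-noise model sits two orders of magnitude below it.

The modality diagnostic counts strict local maxima of the ISI mass function
whose bin mass exceeds 1% of the total; two or more flags a bimodal
(bursting) distribution. The threshold is a visual-judgment stand-in and is
configurable.

## Parameter matching

Deterministic constants are pinned by `A·τ = v·T₁` (enforced to `10⁻⁹`
relative in `MatchedModel`), with `v = 1.845 V` kept as the published
convention — SCCs are invariant to it. The noise family comes from the
pattern label, the magnitude preferentially from the lag ratio `ρ₂/ρ₁`
(fallback: `a = ±(1 + 2ρ₁)`), the power from the CV through the linearized
variance `Var(ISI) = 2(R₀ − R₁)/m²` or from an SNR. `match_and_verify`
iterates (≤ 20 rounds) because grid quantization and the exponential
nonlinearity shift the achieved `ρ₁` away from the closed form: a secant
step on `a` (bounded to `(0, 0.98]`) against the `ρ₁` mismatch, and a
multiplicative rescale of `R₀` against the CV mismatch — `R₀` only, never
`a`. Non-convergence returns the best candidate, flagged.

## EOD-quantization sensitivity

The emission discipline on the grid is not uniquely determined by the
model statement, and the grid-locked `ρ₁` depends on it. Measured values
(3×10⁵ intervals, matched-model parameter sets; "feedback" = quantization
feeds back into the barrier state, "resample" = continuous dynamics with
times rounded afterwards):

| configuration | continuous | feedback + ceil (default) | feedback + nearest | resample nearest | jump at crossing |
|---|---|---|---|---|---|
| Type I (a=0.4, EOD 1.06) | −0.296 | −0.363 | −0.363 | −0.368 | −0.365 |
| Type II mod. (a=0.29, EOD 1.31) | −0.634 | −0.576 | −0.571 | −0.598 | −0.589 |
| Type II strong (a=0.69, EOD 1.04) | −0.809 | −0.779 | −0.777 | −0.782 | −0.784 |

Quantization moves `ρ₁` toward `−1/2` from either side (it superimposes a
differenced, roughly white timing perturbation) while the 15-lag sum stays
near `−1/2` in all disciplines. The default (ceiling to the next free
cycle, jump applied at emission) is the one that also enforces the
one-spike-per-cycle constraint mechanistically. Seed-to-seed scatter of the
systematic values is ±0.002 at 5×10⁵ intervals.

## Problem sizes, tolerances, defaults

* Simulated statistics use 1–5×10⁵ intervals; at `M = 2000` this gives
  50–250 blocks and SCC standard errors of 0.001–0.003, so "within 3 s.e."
  checks resolve effects at the 0.01 level.
* Linearized runs use SNR 45–50 dB. At the matched-model powers
  (SNR 26–35 dB) the threshold-difference excursions exceed `A` a handful
  of times per 10⁵ draws, which the linearized rule treats as a hard
  domain error; SCC patterns are invariant to the power, so weaker noise
  loses nothing. The exponential simulators run at the published powers.
* Classification tolerance defaults to 0.02 (≈ estimator scatter at
  ~2.5×10⁵ spikes); round-trip and PSD tolerances are `10⁻⁸` relative;
  Durbin singularity guard `10⁻¹²`.
* Estimated SCC sequences may exceed `|ρ| = 1` by finite-sample noise
  (warning); theoretical constructors enforce the bound strictly.

## What the synthetic data does and does not show

The fixture generator reproduces the *model's* study conditions: rates,
EOD locking, uni/bimodal interval distributions and the three SCC
patterns. It does not emulate measurement artifacts of real recordings
(spike-sorting errors, drift in the mean ISI, missing cycles), rate–CV
covariation across a population, or higher-order Markov structure beyond
what AR(1) threshold noise induces. Passing tests therefore validate the
implementation and the internal consistency of the theory, not the claim
that any particular biological afferent is described by AR(1) threshold
noise.

## Known limitations

* Inputs are constant (DC) only; no time-varying stimuli.
* The AR(1) families cannot produce positive `ρ₁` (the coefficient is
  confined to `(−1, 1)`); arbitrary PSD noise ACFs can extend the reachable
  patterns via `generate_from_acf`, but no higher-order AR fitting is
  provided.
* The inverse solver's boundary closure assumes the noise decorrelates at
  the horizon; prescriptions whose partial sum is far from `−1/2` yield a
  large consistency residual rather than a "best" extrapolation.
* SCCs in this model are invariant to the firing rate by construction; the
  empirical rate-dependence of correlations in real afferents is outside
  the model class.
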