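"""Dynamic-threshold spike generators.

The encoder is a non-resetting adaptive ("dynamic") threshold model of a
spontaneously firing neuron. A constant bias voltage ``v`` drives a spike
generator that is gated by a moving barrier r(t): after every spike the
barrier jumps by ``A`` volts and then relaxes exponentially toward zero with
time constant ``tau``, never being reset. A spike is emitted whenever the
coding error e(t) = v - r(t) reaches the spike threshold ``gamma``. Because
r(t) sums the whole spiking history, the train carries memory, and making
``gamma`` a correlated random sequence (one draw per interval) produces the
negative serial correlations between interspike intervals (ISIs) observed in
high-rate sensory afferents such as the P-type electroreceptor afferents of
weakly electric fish.

Two simulators are provided:

``simulate_linearized``
    Replaces the exponential relaxation by its tangent line of slope
    ``-m = -(v - gamma + A)/tau``, giving the exact update
    ``ISI_i = (g_i - g_{i-1} + A)/m`` for threshold-noise deviations ``g_i``.
    This is the regime in which the closed-form correlation theory of
    :mod:`dynthresh.theory` is exact. Fully vectorized.

``simulate_exponential``
    Event-driven simulation of the full exponential relaxation with the exact
    logarithmic crossing time per interval (no time stepping, so no dt
    tolerance). Optionally the emitted spike times are quantized to an
    electric-organ-discharge (EOD) grid: the spike is emitted at the first
    grid point at or after the continuous crossing, which enforces at most
    one spike per EOD cycle.

Internal time unit is milliseconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ParameterError

__all__ = [
    "ModelParams",
    "EODGrid",
    "SpikeTrain",
    "ISISequence",
    "ThresholdTrace",
    "TauSequence",
    "simulate_deterministic",
    "simulate_linearized",
    "simulate_exponential",
    "simulate_isis",
    "tau_sequence_from_threshold_noise",
    "threshold_trace",
]

#: ISIs discarded at the start of a run before statistics are computed, so the
#: threshold state and AR noise have forgotten the initial condition.
DEFAULT_BURN_IN = 100


@dataclass(frozen=True)
class ModelParams:
    """Constants of the deterministic encoder.

    Parameters
    ----------
    v : float
        Constant bias voltage (volts), > 0.
    A : float
        Jump of the dynamic threshold after each spike (volts), > 0.
    tau : float
        Relaxation time constant of the dynamic threshold (ms), > 0.
    gamma : float, optional
        Mean spike threshold (volts). Defaults to ``A/2``, the value that
        minimizes the mean-squared coding error; the serial correlations do
        not depend on it. Must satisfy ``v - gamma > 0`` or the exponential
        model never fires.
    """

    v: float
    A: float
    tau: float
    gamma: float | None = None

    def __post_init__(self):
        if self.gamma is None:
            object.__setattr__(self, "gamma", self.A / 2.0)
        if self.v <= 0:
            raise ParameterError(f"bias voltage v must be > 0, got {self.v}")
        if self.A <= 0:
            raise ParameterError(f"threshold jump A must be > 0, got {self.A}")
        if self.tau <= 0:
            raise ParameterError(f"time constant tau must be > 0, got {self.tau}")
        if self.v - self.gamma <= 0:
            raise ParameterError(
                f"v - gamma must be > 0 for the threshold to be crossed "
                f"(v={self.v}, gamma={self.gamma})"
            )

    @property
    def m(self) -> float:
        """Slope (v - gamma + A)/tau of the linearized threshold decay (V/ms)."""
        return (self.v - self.gamma + self.A) / self.tau

    @property
    def isi_linearized(self) -> float:
        """Deterministic ISI of the linearized rule, A*tau/(v - gamma + A) (ms)."""
        return self.A / self.m

    @property
    def isi_exponential(self) -> float:
        """Deterministic ISI of the exponential rule,
        tau * ln((v - gamma + A)/(v - gamma)) (ms)."""
        return self.tau * math.log((self.v - self.gamma + self.A) / (self.v - self.gamma))

    def as_dict(self) -> dict:
        return {"v": self.v, "A": self.A, "tau": self.tau, "gamma": self.gamma}


@dataclass(frozen=True)
class EODGrid:
    """Electric-organ-discharge time base.

    When ``enabled``, spike times are constrained to integer multiples of
    ``period`` (ms) and successive spikes are at least one period apart —
    the "at most one spike per EOD cycle" firing of P-type afferents.
    """

    period: float
    enabled: bool = True

    def __post_init__(self):
        if self.enabled and self.period <= 0:
            raise ParameterError(f"EOD period must be > 0, got {self.period}")


@dataclass
class SpikeTrain:
    """Spike times in ms, strictly increasing, with their time base."""

    times: np.ndarray
    time_base: str = "continuous"  # "continuous" | "eod_grid"
    eod_period: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise ParameterError("a spike train needs at least 2 spikes to yield ISIs")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ParameterError(f"spike times must be strictly increasing (index {bad})")
        if self.time_base == "eod_grid" and not self.eod_period:
            raise ParameterError("eod_grid time base requires eod_period")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self, unit: str = "ms") -> "ISISequence":
        """Successive intervals; ``unit='eod'`` divides by the EOD period and
        rounds to the (exact) integer cycle counts."""
        d = np.diff(self.times)
        if unit == "eod":
            if not self.eod_period:
                raise ParameterError("no EOD period attached to this train")
            d = np.rint(d / self.eod_period)
        return ISISequence(d, unit=unit)


@dataclass
class ISISequence:
    """Interspike intervals with a mandatory unit tag (``"ms"`` or ``"eod"``)."""

    intervals: np.ndarray
    unit: str = "ms"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.unit not in ("ms", "eod"):
            raise ParameterError(f"unknown ISI unit {self.unit!r}")
        if self.intervals.size and np.any(self.intervals <= 0):
            bad = int(np.argmax(self.intervals <= 0))
            raise DomainError(f"nonpositive ISI at index {bad}", index=bad)
        if self.unit == "eod" and self.intervals.size:
            if not np.allclose(self.intervals, np.rint(self.intervals)):
                raise ParameterError("EOD-unit ISIs must be positive integers")

    def __len__(self):
        return int(self.intervals.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.intervals))

    @property
    def cv(self) -> float:
        """Coefficient of variation sqrt(Var)/mean."""
        return float(np.std(self.intervals) / np.mean(self.intervals))


@dataclass
class ThresholdTrace:
    """Diagnostic sampling of the dynamic threshold between spikes."""

    times: np.ndarray
    r: np.ndarray  # dynamic threshold r(t), volts
    e: np.ndarray  # coding error e(t) = v - r(t), volts


@dataclass
class TauSequence:
    """Per-interval time constants of the equivalent noisy-tau encoder."""

    tau_i: np.ndarray  # ms
    m_i: np.ndarray  # V/ms


def _noise_values(noise) -> np.ndarray:
    """Accept a NoiseSequence or a plain array of threshold deviations (volts)."""
    vals = getattr(noise, "values", noise)
    return np.asarray(vals, dtype=float)


def simulate_deterministic(params: ModelParams, n_spikes: int) -> SpikeTrain:
    """Noise-free train under the linearized rule: every ISI equals A/m.

    The train starts at t0 = 0 and contains ``n_spikes`` spikes.
    """
    if n_spikes < 2:
        raise ParameterError("n_spikes must be >= 2")
    isi = params.isi_linearized
    times = isi * np.arange(n_spikes, dtype=float)
    return SpikeTrain(times, meta={"params": params.as_dict(), "rule": "deterministic"})


def simulate_linearized(params: ModelParams, noise, seed=None) -> ISISequence:
    """Linearized stochastic train: ISI_i = (g_i - g_{i-1} + A)/m.

    ``noise`` supplies the threshold deviations g_i about the mean gamma
    (length n+1 for n intervals). The draw timing convention is that g_i is
    drawn immediately after spike i-1 and held until spike i. Any
    nonpositive interval raises :class:`DomainError` naming the offending
    index — the linearization is only valid for noise small against A.

    ``seed`` is accepted for interface symmetry; the simulator itself is
    deterministic given the noise realization.
    """
    g = _noise_values(noise)
    if g.size < 2:
        raise ParameterError("need at least 2 noise values for 1 interval")
    isis = (np.diff(g) + params.A) / params.m
    bad = np.nonzero(isis <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise DomainError(
            f"nonpositive ISI at interval {i}: threshold noise too large for "
            f"the linearized rule (|g_i - g_(i-1)| must stay below A)",
            index=i,
        )
    return ISISequence(isis, unit="ms", meta={"params": params.as_dict(), "rule": "linearized"})


def simulate_exponential(
    params: ModelParams,
    noise,
    grid: EODGrid | None = None,
    seed=None,
) -> SpikeTrain:
    """Event-driven simulation of the exponential dynamic threshold.

    Between spikes the barrier is ``r(t) = p * exp(-(t - t_prev)/tau)`` where
    ``p`` is its post-spike value. The next continuous crossing with the
    realized spike threshold ``gamma + g_i`` is at

        ``ISI_i = tau * ln(p / (v - gamma - g_i))``

    solved in closed form (no integration grid). With an enabled EOD grid the
    spike is emitted at the first grid point at or after the crossing, never
    in the cycle of the previous spike, and the threshold jump ``A`` is
    applied to the barrier value at the actual emission time.

    The train starts at t0 = 0 with the barrier at its post-spike value
    ``v - (gamma + g_0) + A``; the number of intervals is ``len(noise) - 1``.
    """
    g = _noise_values(noise)
    if g.size < 2:
        raise ParameterError("need at least 2 noise values for 1 interval")
    v, A, tau, gamma = params.v, params.A, params.tau, params.gamma
    realized = gamma + g  # realized spike thresholds, one per interval
    if np.any(v - realized <= 0):
        i = int(np.argmax(v - realized <= 0))
        raise DomainError(
            f"v - realized threshold <= 0 at index {i}: no crossing exists", index=i
        )

    use_grid = grid is not None and grid.enabled
    period = grid.period if use_grid else None
    n = g.size - 1
    times = np.empty(n + 1)
    times[0] = 0.0
    peak = v - realized[0] + A  # barrier just after the t0 spike
    t_prev = 0.0
    idx_prev = 0  # grid index of previous spike
    log = math.log
    exp = math.exp
    for i in range(1, n + 1):
        target = v - realized[i]
        if peak <= target:
            # barrier already below threshold level: immediate crossing
            if not use_grid:
                raise DomainError(
                    f"no positive crossing time at interval {i}: noise too "
                    f"large for the exponential rule",
                    index=i,
                )
            t_cross = t_prev
        else:
            t_cross = t_prev + tau * log(peak / target)
        if use_grid:
            idx = int(math.ceil(t_cross / period - 1e-12))
            if idx <= idx_prev:
                idx = idx_prev + 1  # at most one spike per EOD cycle
            t_spike = idx * period
            idx_prev = idx
        else:
            t_spike = t_cross
        # barrier decayed to the emission time, then jumps by A
        r_emit = peak * exp(-(t_spike - t_prev) / tau)
        peak = r_emit + A
        times[i] = t_spike
        t_prev = t_spike

    meta = {
        "params": params.as_dict(),
        "rule": "exponential",
        "seed": getattr(noise, "seed", seed),
    }
    if use_grid:
        return SpikeTrain(times, time_base="eod_grid", eod_period=period, meta=meta)
    return SpikeTrain(times, time_base="continuous", meta=meta)


def simulate_isis(
    params: ModelParams,
    spec,
    n_isis: int,
    seed,
    grid: EODGrid | None = None,
    rule: str = "exponential",
    burn_in: int = DEFAULT_BURN_IN,
) -> ISISequence:
    """Convenience pipeline: draw AR threshold noise, simulate, drop burn-in.

    Parameters
    ----------
    spec : dynthresh.noise.ARNoiseSpec
        Threshold-noise process definition.
    rule : {"exponential", "linearized"}
        Which simulator to run. The EOD grid only applies to the exponential
        rule.
    burn_in : int
        ISIs discarded at the start before returning.

    Returns the ISI sequence in ms (continuous/linearized) or in integer EOD
    cycles when simulated on an enabled grid.
    """
    from .noise import generate_ar1  # local import to avoid a cycle

    nseq = generate_ar1(spec, n_isis + burn_in + 1, seed)
    if rule == "linearized":
        isis = simulate_linearized(params, nseq)
        out = ISISequence(isis.intervals[burn_in:], unit="ms", meta=isis.meta)
    elif rule == "exponential":
        train = simulate_exponential(params, nseq, grid=grid)
        unit = "eod" if train.time_base == "eod_grid" else "ms"
        isis = train.isis(unit=unit)
        out = ISISequence(isis.intervals[burn_in:], unit=unit, meta=train.meta)
    else:
        raise ParameterError(f"unknown rule {rule!r}")
    out.meta.update({"noise": spec.as_dict(), "seed": seed, "burn_in": burn_in})
    return out


def tau_sequence_from_threshold_noise(params: ModelParams, noise) -> TauSequence:
    """Map threshold noise to the equivalent per-interval time constants.

    The encoder with a fixed spike threshold and a random relaxation time
    constant ``tau_i = (tau/A) * (g_i - g_{i-1} + A)`` produces, under the
    linearized rule, exactly the same spike times as the noisy-threshold
    encoder driven by the deviations ``g_i``. The per-interval slopes are
    ``m_i = (v - gamma + A)/tau_i``. Consequently the serial correlations of
    the ``tau_i`` equal those of the ISIs.
    """
    g = _noise_values(noise)
    if g.size < 2:
        raise ParameterError("need at least 2 noise values for 1 interval")
    tau_i = (params.tau / params.A) * (np.diff(g) + params.A)
    bad = np.nonzero(tau_i <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise DomainError(f"nonpositive tau at interval {i}: noise too large", index=i)
    m_i = (params.v - params.gamma + params.A) / tau_i
    return TauSequence(tau_i=tau_i, m_i=m_i)


def threshold_trace(
    params: ModelParams, train: SpikeTrain, noise, samples_per_isi: int = 20
) -> ThresholdTrace:
    """Reconstruct r(t) and e(t) = v - r(t) along a simulated exponential train.

    Diagnostic only: replays the barrier decay between the recorded spike
    times using the same noise realization that generated the train.
    """
    g = _noise_values(noise)
    t = train.times
    v, A, tau, gamma = params.v, params.A, params.tau, params.gamma
    peak = v - (gamma + g[0]) + A
    ts, rs = [], []
    for i in range(1, t.size):
        seg = np.linspace(t[i - 1], t[i], samples_per_isi, endpoint=False)
        r = peak * np.exp(-(seg - t[i - 1]) / tau)
        ts.append(seg)
        rs.append(r)
        peak = peak * math.exp(-(t[i] - t[i - 1]) / tau) + A
    times = np.concatenate(ts)
    r = np.concatenate(rs)
    return ThresholdTrace(times=times, r=r, e=v - r)
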