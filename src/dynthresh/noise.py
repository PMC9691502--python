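"""Threshold-noise processes and their autocorrelation functions.

The spike threshold receives one noise draw per interspike interval, so the
natural noise model is a discrete wide-sense-stationary sequence indexed by
spike count, with discrete autocorrelation R_k at lag k (in units of the mean
ISI). The workhorse is the first-order autoregressive (AR(1)) family

    g_k = s * a * g_{k-1} + w_k,      0 <= a < 1,  s in {+1, -1},

the discrete sampling of an Ornstein-Uhlenbeck relaxation at the mean ISI:
a = exp(-T1/tau_g) for relaxation time tau_g. Slow noise (s = +1) yields the
monotone negative "Type I" ISI correlation pattern; fast, sign-alternating
noise (s = -1) yields the damped-oscillatory "Type II" pattern; a = 0 (white
noise) yields the degenerate "Type III" pattern. Innovations are Gaussian.

``generate_from_acf`` samples a stationary Gaussian sequence with an
*arbitrary* prescribed autocorrelation out to lag K — the plumbing needed to
simulate from the output of the inverse problem (ISI correlations -> noise
autocorrelation) solved in :mod:`dynthresh.theory`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_toeplitz, toeplitz
from scipy.signal import lfilter, lfiltic

from .errors import ParameterError, ValidityError

__all__ = ["ARNoiseSpec", "NoiseSequence", "NoiseACF", "acf_ar1", "generate_ar1",
           "generate_from_acf", "snr_to_power", "power_to_snr"]


def snr_to_power(snr_db: float, v: float) -> float:
    """Noise power R0 (V^2) from a signal-to-noise ratio 10*log10(v^2/R0) in dB."""
    return v**2 * 10.0 ** (-snr_db / 10.0)


def power_to_snr(r0: float, v: float) -> float:
    """SNR in dB, 10*log10(v^2/R0)."""
    return 10.0 * math.log10(v**2 / r0)


@dataclass(frozen=True)
class ARNoiseSpec:
    """AR(1) threshold-noise definition.

    Parameters
    ----------
    a : float
        Magnitude of the AR coefficient, in [0, 1). ``a = 0`` is white noise.
    sign : int
        +1 for slow (low-pass, Type I) noise, -1 for fast (alternating,
        Type II) noise, 0 for white (Type III).
    r0 : float
        Target noise power R0 = Var(g) in V^2.
    """

    a: float
    sign: int = +1
    r0: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.a < 1.0):
            raise ParameterError(f"AR magnitude a must be in [0, 1), got {self.a}")
        if self.sign not in (-1, 0, +1):
            raise ParameterError(f"sign must be -1, 0 or +1, got {self.sign}")
        if self.r0 <= 0:
            raise ParameterError(f"noise power R0 must be > 0, got {self.r0}")
        if self.sign == 0 and self.a != 0.0:
            raise ParameterError("white noise (sign=0) requires a = 0")

    @classmethod
    def from_snr(cls, a: float, sign: int, snr_db: float, v: float) -> "ARNoiseSpec":
        """Specify the power through the SNR convention 10*log10(v^2/R0)."""
        return cls(a=a, sign=sign, r0=snr_to_power(snr_db, v))

    @property
    def coeff(self) -> float:
        """Signed AR coefficient s*a."""
        return self.sign * self.a

    def tau_gamma(self, t1: float) -> float:
        """Relaxation time -T1/ln(a) (ms) of the underlying continuous process."""
        if self.a == 0.0:
            return 0.0
        return -t1 / math.log(self.a)

    @property
    def innovation_var(self) -> float:
        """Variance of the Gaussian innovations implied by (a, R0)."""
        return self.r0 * (1.0 - self.a**2)

    def as_dict(self) -> dict:
        return {"a": self.a, "sign": self.sign, "r0": self.r0}


@dataclass
class NoiseSequence:
    """A realization of a threshold-noise process (deviations about gamma, V)."""

    values: np.ndarray
    spec: object = None
    seed: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return int(self.values.size)


@dataclass
class NoiseACF:
    """Discrete autocorrelation R_k, k = 0..K (lags in units of the mean ISI)."""

    values: np.ndarray  # R_k in V^2 (or dimensionless when normalized)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1 or self.values[0] <= 0:
            raise ParameterError("ACF needs R0 > 0 at lag 0")

    @property
    def r0(self) -> float:
        return float(self.values[0])

    @property
    def max_lag(self) -> int:
        return int(self.values.size - 1)

    def normalized_copy(self) -> "NoiseACF":
        return NoiseACF(self.values / self.r0, normalized=True)

    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue of the Toeplitz covariance built from R_0..R_K."""
        return float(np.linalg.eigvalsh(toeplitz(self.values)).min())

    def check_psd(self, tol: float = 1e-8) -> None:
        """Raise :class:`ValidityError` unless the ACF is PSD up to -tol*R0."""
        if self.min_eigenvalue() < -tol * self.r0:
            raise ValidityError(
                "autocorrelation sequence is not positive semidefinite "
                f"(min Toeplitz eigenvalue {self.min_eigenvalue():.3e})"
            )


def acf_ar1(spec: ARNoiseSpec, K: int) -> NoiseACF:
    """Theoretical AR(1) autocorrelation R_k = R0 * (s*a)^k for k = 0..K.

    For unit innovation variance the unscaled form is (s*a)^k / (1 - a^2);
    here the sequence is scaled so that lag 0 equals the spec's target power.
    White noise (sign 0) gives R = (R0, 0, 0, ...).
    """
    if K < 0:
        raise ParameterError("K must be >= 0")
    k = np.arange(K + 1)
    if spec.sign == 0:
        vals = np.zeros(K + 1)
        vals[0] = spec.r0
    else:
        vals = spec.r0 * spec.coeff ** k
    return NoiseACF(vals)


def generate_ar1(spec: ARNoiseSpec, n: int, seed) -> NoiseSequence:
    """Sample n values of the AR(1) threshold noise.

    The first sample is drawn from the stationary distribution N(0, R0), so
    the sequence is wide-sense stationary from sample 1 (no transient).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.a == 0.0:
        x = rng.normal(0.0, math.sqrt(spec.r0), size=n)
        return NoiseSequence(x, spec=spec, seed=seed)
    phi = spec.coeff
    sd_w = math.sqrt(spec.innovation_var)
    x0 = rng.normal(0.0, math.sqrt(spec.r0))
    w = rng.normal(0.0, sd_w, size=n)
    # x_k = phi x_{k-1} + w_k, fed with the stationary initial state
    x, _ = lfilter([1.0], [1.0, -phi], w, zi=np.array([phi * x0]))
    return NoiseSequence(x, spec=spec, seed=seed)


def generate_from_acf(
    acf: NoiseACF, n: int, seed, psd_tol: float = 1e-8, jitter_tol: float = 1e-10
) -> NoiseSequence:
    """Sample a stationary Gaussian sequence with prescribed ACF at lags 0..K.

    The prescribed R_0..R_K is extended beyond lag K by its maximum-entropy
    (autoregressive) completion: the Yule-Walker system on the Toeplitz
    covariance gives AR(K) coefficients whose stationary process reproduces
    the input ACF *exactly* at lags 0..K and decays geometrically beyond.
    The first K samples are drawn from the exact joint Gaussian (Cholesky of
    the Toeplitz head) and the rest by the O(n) recursion.

    Near-singular input (smallest Toeplitz eigenvalue below ``jitter_tol*R0``)
    is regularized by a diagonal jitter recorded in the output metadata; an
    indefinite input (eigenvalue below ``-psd_tol*R0``) raises
    :class:`ValidityError`.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    r = np.array(acf.values, dtype=float)
    r0 = r[0]
    min_eig = float(np.linalg.eigvalsh(toeplitz(r)).min())
    if min_eig < -psd_tol * r0:
        raise ValidityError(
            f"indefinite ACF: min Toeplitz eigenvalue {min_eig:.3e} < -{psd_tol}*R0"
        )
    jitter = 0.0
    if min_eig < jitter_tol * r0:
        jitter = jitter_tol * r0 - min_eig
        r[0] += jitter

    rng = np.random.default_rng(seed)
    K = r.size - 1
    if K == 0:
        x = rng.normal(0.0, math.sqrt(r[0]), size=n)
        return NoiseSequence(x, seed=seed, meta={"jitter": jitter})

    # Yule-Walker AR(K) fit: phi solves T(r[0..K-1]) phi = r[1..K]
    phi = solve_toeplitz(r[:-1], r[1:])
    sigma2 = float(r[0] - phi @ r[1:])
    if sigma2 <= 0:
        raise ValidityError("nonpositive innovation variance; ACF too close to singular")

    head = min(K, n)
    C = toeplitz(r[:head])
    L = cholesky(C + np.eye(head) * jitter_tol * r[0], lower=True)
    x_init = L @ rng.normal(size=head)
    if n <= K:
        return NoiseSequence(x_init[:n], seed=seed, meta={"jitter": jitter})

    a_poly = np.concatenate(([1.0], -phi))
    w = rng.normal(0.0, math.sqrt(sigma2), size=n - K)
    zi = lfiltic([1.0], a_poly, x_init[::-1])
    x_rest, _ = lfilter([1.0], a_poly, w, zi=zi)
    x = np.concatenate([x_init, x_rest])
    return NoiseSequence(x, seed=seed, meta={"jitter": jitter, "ar_order": K})
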