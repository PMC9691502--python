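"""Closed-form theory linking threshold-noise autocorrelation and ISI SCCs.

Under the linearized dynamic-threshold rule the i-th interspike interval is
``ISI_i = (g_i - g_{i-1} + A)/m``, a first difference of the threshold-noise
sequence plus a constant. The serial correlation coefficients (SCCs) of the
ISIs therefore follow from the noise autocorrelation R_k alone:

    rho_0 = 1,
    rho_k = -(R_{k-1} - 2 R_k + R_{k+1}) / (2 (R_0 - R_1)),   k >= 1.

This forward map is scale invariant in R and independent of every
deterministic encoder parameter (v, gamma, A, tau). Because the numerator is
a second difference, the SCC sum telescopes: whenever the noise decorrelates
(R_N -> 0) the limiting sum of SCCs is exactly -1/2, which in turn makes the
spike-train power spectrum vanish at zero frequency (a perfect DC block).

For AR(1) noise the map evaluates to the two closed-form geometric families

    Type I  (coefficient +a): rho_k = -a^(k-1) (1 - a) / 2    (monotone, negative)
    Type II (coefficient -a): rho_k = -(-a)^(k-1) (1 + a) / 2 (alternating, damped)

and a = 0 degenerates to Type III (rho_1 = -1/2, rest zero). The inverse
problem — recover R_k from a prescribed SCC sequence — is solved in closed
form by integrating the second-difference recurrence with boundary pair
R_0 = 1, R_{K+1} = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DomainError, ParameterError, UnfittablePatternError
from .noise import NoiseACF

__all__ = [
    "SCCSequence",
    "ISIStats",
    "PatternLabel",
    "InverseResult",
    "scc_from_acf",
    "scc_type1",
    "scc_type2",
    "acf_from_scc",
    "estimate_a",
    "limiting_sum",
    "dc_power",
    "classify_pattern",
]

#: Default classification tolerance; about the estimator scatter at ~2.5e5 spikes.
CLASSIFY_TOL = 0.02


class PatternLabel(str, Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    TYPE_III = "TYPE_III"
    OTHER = "OTHER"


@dataclass
class SCCSequence:
    """Serial correlation coefficients rho_k, k = 0..K (rho_0 = 1).

    ``kind`` distinguishes theoretical sequences (|rho_k| <= 1 enforced) from
    estimated ones (finite-sample excursions past 1 only warn). Estimators
    attach per-lag standard errors in ``se`` and the number of blocks used.
    """

    rho: np.ndarray
    kind: str = "theoretical"
    se: np.ndarray | None = None
    n_blocks: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.size < 1 or abs(self.rho[0] - 1.0) > 1e-12:
            raise ParameterError("SCC sequence must start with rho_0 = 1")
        over = np.abs(self.rho) > 1.0 + 1e-12
        if over.any():
            if self.kind == "theoretical":
                raise ParameterError(
                    f"|rho_k| > 1 at lag {int(np.argmax(over))} in a theoretical sequence"
                )
            warnings.warn("estimated |rho_k| exceeds 1 (finite-sample noise)")

    @property
    def max_lag(self) -> int:
        return int(self.rho.size - 1)

    def __getitem__(self, k):
        return self.rho[k]


@dataclass(frozen=True)
class ISIStats:
    """Mean/variance summary of an ISI sequence (time unit of the caller)."""

    t1: float  # mean ISI
    v1: float  # ISI variance

    def __post_init__(self):
        if self.t1 <= 0:
            raise ParameterError("mean ISI must be > 0")
        if self.v1 < 0:
            raise ParameterError("ISI variance must be >= 0")

    @property
    def cv(self) -> float:
        return float(np.sqrt(self.v1) / self.t1)

    def kth_interval_mean(self, k: int) -> float:
        """Mean of the k-th order interval, k * T1."""
        return k * self.t1


@dataclass
class InverseResult:
    """Output of :func:`acf_from_scc`.

    ``acf`` carries the R0-normalized solution on lags 0..K+1 (the last value
    is the boundary 0). ``residual`` is |R_{K+2}| obtained by continuing the
    recurrence one step with rho_{K+1} = 0; it vanishes exactly when the
    partial SCC sum equals -1/2, so it measures the inconsistency of the
    prescribed sequence. ``physical`` flags |R_k| <= R0 for all k.
    """

    acf: NoiseACF
    residual: float
    r1: float
    physical: bool


def scc_from_acf(acf: NoiseACF, K: int | None = None) -> SCCSequence:
    """Forward map: SCCs from a noise autocorrelation sequence.

    Needs R at lags 0..K+1 to produce rho at lags 0..K. Degenerate input with
    R_0 = R_1 (zero ISI variance) raises :class:`DomainError`. The result is
    invariant under rescaling of the ACF.
    """
    r = np.asarray(acf.values, dtype=float)
    if K is None:
        K = r.size - 2
    if K < 1 or r.size < K + 2:
        raise ParameterError("need ACF lags 0..K+1 with K >= 1")
    denom = 2.0 * (r[0] - r[1])
    if abs(denom) <= 1e-15 * max(abs(r[0]), 1.0):
        raise DomainError("R0 = R1: zero ISI variance, SCCs undefined")
    k = np.arange(1, K + 1)
    rho = np.empty(K + 1)
    rho[0] = 1.0
    rho[1:] = -(r[k - 1] - 2.0 * r[k] + r[k + 1]) / denom
    return SCCSequence(rho, kind="theoretical")


def _check_a(a: float) -> None:
    if not (0.0 < a < 1.0):
        raise ParameterError(f"AR magnitude a must be in (0, 1), got {a}")


def scc_type1(a: float, K: int) -> SCCSequence:
    """Type I closed form: rho_k = -a^(k-1) (1 - a)/2 for k >= 1.

    All lags negative, magnitudes decaying geometrically toward zero with
    ratio a; rho_1 = -(1 - a)/2 lies in (-1/2, 0).
    """
    _check_a(a)
    k = np.arange(1, K + 1)
    rho = np.empty(K + 1)
    rho[0] = 1.0
    rho[1:] = -(a ** (k - 1)) * (1.0 - a) / 2.0
    return SCCSequence(rho)


def scc_type2(a: float, K: int) -> SCCSequence:
    """Type II closed form: rho_k = -(-a)^(k-1) (1 + a)/2 for k >= 1.

    Alternating signs damped with ratio a; rho_1 = -(1 + a)/2 < -1/2.
    """
    _check_a(a)
    k = np.arange(1, K + 1)
    rho = np.empty(K + 1)
    rho[0] = 1.0
    rho[1:] = -((-a) ** (k - 1)) * (1.0 + a) / 2.0
    return SCCSequence(rho)


def acf_from_scc(sccs: SCCSequence, K: int | None = None, warn_tol: float = 1e-9) -> InverseResult:
    """Inverse map: R0-normalized noise ACF from prescribed SCCs at lags 1..K.

    The forward map is the second-difference recurrence

        R_{k+1} = 2 R_k - R_{k-1} - D rho_k,   D = 2 (R_0 - R_1),

    so with boundary pair R_0 = 1 and R_{K+1} = 0, summing the recurrence
    twice (the discrete Green's function of the second difference) gives R_1
    in closed form:

        R_1 = (K + 2 S) / (K + 1 + 2 S),   S = sum_{j=1..K} (K + 1 - j) rho_j,

    after which the recurrence fills in the remaining lags. D = 0 (rho
    prescribing zero ISI variance) raises :class:`DomainError`. If the
    solution exceeds |R_k| <= R_0 beyond ``warn_tol`` the ACF is flagged
    non-physical with a warning.
    """
    rho = np.asarray(sccs.rho, dtype=float)
    if K is None:
        K = rho.size - 1
    if K < 1 or rho.size < K + 1:
        raise ParameterError("need SCCs at lags 1..K with K >= 1")
    j = np.arange(1, K + 1)
    S = float(np.sum((K + 1 - j) * rho[j]))
    denom = K + 1 + 2.0 * S
    if abs(denom) <= 1e-14:
        raise DomainError("degenerate inverse: K + 1 + 2*S = 0")
    r1 = (K + 2.0 * S) / denom
    D = 2.0 * (1.0 - r1)
    if abs(D) <= 1e-14:
        raise DomainError("degenerate inverse: D = 2(R0 - R1) = 0")
    R = np.empty(K + 2)
    R[0], R[1] = 1.0, r1
    for k in range(1, K + 1):
        R[k + 1] = 2.0 * R[k] - R[k - 1] - D * rho[k]
    # continue one step with rho_{K+1} = 0; equals -R_K by the boundary
    residual = abs(2.0 * R[K + 1] - R[K])
    physical = bool(np.all(np.abs(R) <= 1.0 + warn_tol))
    if not physical:
        warnings.warn(
            "inverse solution violates |R_k| <= R0: prescribed SCCs are not "
            "realizable by a wide-sense stationary threshold noise"
        )
    return InverseResult(acf=NoiseACF(R, normalized=True), residual=residual,
                         r1=r1, physical=physical)


def estimate_a(sccs: SCCSequence, method: str = "ratio",
               pattern: PatternLabel | None = None) -> tuple[float, bool]:
    """Estimate the AR(1) magnitude a from SCCs.

    ``method="rho1"`` inverts the closed forms at lag 1 (Type I: a = 1 +
    2 rho_1; Type II: a = -(1 + 2 rho_1)); ``method="ratio"`` uses the
    usually more robust lag ratio (Type I: a = rho_2/rho_1; Type II:
    a = -rho_2/rho_1). Returns ``(a, clipped)`` with a clipped into [0, 1)
    and a flag when clipping occurred.
    """
    rho = sccs.rho
    if rho.size < 3 and method == "ratio":
        raise ParameterError("ratio method needs lags 1 and 2")
    if pattern is None:
        pattern = classify_pattern(sccs)
    rho1 = float(rho[1])
    if not (-1.0 < rho1 < 0.0):
        raise ParameterError(f"rho_1 must be in (-1, 0), got {rho1}")
    if pattern is PatternLabel.TYPE_III and method == "ratio":
        raise UnfittablePatternError("ratio a = rho_2/rho_1 is 0/0-undefined for Type III")
    sign = -1.0 if pattern is PatternLabel.TYPE_II else 1.0
    if method == "rho1":
        a = sign * (1.0 + 2.0 * rho1)
    elif method == "ratio":
        if rho1 == 0.0:
            raise ParameterError("rho_1 = 0: ratio undefined")
        a = sign * float(rho[2]) / rho1
    else:
        raise ParameterError(f"unknown method {method!r}")
    clipped = not (0.0 <= a < 1.0)
    a = float(np.clip(a, 0.0, 1.0 - 1e-12))
    return a, clipped


def limiting_sum(sccs: SCCSequence) -> np.ndarray:
    """Cumulative partial sums sum_{k=1..j} rho_k for j = 1..K.

    For any SCC sequence produced by the forward map from a decorrelating
    noise ACF the total telescopes to -1/2 up to the truncation tail."""
    return np.cumsum(sccs.rho[1:])


def dc_power(stats: ISIStats, sccs: SCCSequence) -> float:
    """Zero-frequency limit of the spike-train power spectrum.

    P(0) = C^2/(2 pi T1) * (1 + 2 sum_k rho_k); the sum uses all supplied
    lags. With the limiting sum -1/2 this is an exact DC block (zero)."""
    total = float(np.sum(sccs.rho[1:]))
    return stats.cv**2 / (2.0 * np.pi * stats.t1) * (1.0 + 2.0 * total)


def classify_pattern(sccs: SCCSequence, tol: float = CLASSIFY_TOL) -> PatternLabel:
    """Assign the SCC pattern label.

    TYPE_III: rho_1 within tol of -1/2 and all later lags within tol of 0.
    TYPE_I: -1/2 < rho_1 < 0 with rho_2 not significantly positive.
    TYPE_II: rho_1 < -1/2 with rho_2 > 0. Anything else: OTHER.
    """
    rho = sccs.rho
    if rho.size < 3:
        raise ParameterError("classification needs lags 1 and 2")
    rho1, rho2 = float(rho[1]), float(rho[2])
    if abs(rho1 + 0.5) <= tol and np.all(np.abs(rho[2:]) <= tol):
        return PatternLabel.TYPE_III
    if -0.5 < rho1 < 0.0 and rho2 < tol:
        return PatternLabel.TYPE_I
    if rho1 < -0.5 and rho2 > 0.0:
        return PatternLabel.TYPE_II
    return PatternLabel.OTHER
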