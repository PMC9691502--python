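"""Matching model parameters to a target spike train.

The deterministic encoder constants are pinned by the mean-rate identity
A*tau = v*T1 (one free degree of freedom once v is fixed), the noise family
and magnitude by the observed pattern and the first two serial correlation
coefficients, and the noise power by the ISI coefficient of variation or an
SNR. ``match_and_verify`` closes the loop: it simulates the matched model on
the EOD grid, re-estimates the statistics, and iterates on (a, R0), because
grid quantization and the exponential nonlinearity shift the achieved rho_1
away from the linearized closed form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError, UnfittablePatternError
from .model import EODGrid, ModelParams, simulate_isis
from .noise import ARNoiseSpec, snr_to_power
from .stats import SCCEstimatorConfig, estimate_sccs
from .theory import PatternLabel, SCCSequence, classify_pattern, estimate_a

__all__ = ["TargetStats", "MatchedModel", "fit_deterministic", "fit_noise",
           "match_and_verify"]

#: Default bias voltage (V). Arbitrary — the SCCs are invariant to it — but
#: kept at the value used for the published matched configurations.
DEFAULT_V = 1.845


@dataclass(frozen=True)
class TargetStats:
    """Summary statistics a matched model should reproduce.

    T1 and the EOD period share the same unit (ms); rho_1, rho_2 and the CV
    are dimensionless.
    """

    t1: float
    cv: float
    rho1: float
    rho2: float
    eod_period: float | None = None

    def __post_init__(self):
        if self.t1 <= 0 or self.cv < 0:
            raise ParameterError("need T1 > 0 and CV >= 0")


@dataclass
class MatchedModel:
    """A fully specified model plus the statistics it achieved."""

    params: ModelParams
    noise: ARNoiseSpec
    grid: EODGrid | None
    target: TargetStats
    achieved: dict
    converged: bool
    n_iter: int
    seed: object = None

    def __post_init__(self):
        # linearized matching identity must hold to numerical precision
        lhs = self.params.A * self.params.tau
        rhs = self.params.v * self.target.t1
        if abs(lhs - rhs) > 1e-9 * abs(rhs):
            warnings.warn(
                f"A*tau = {lhs:.6g} deviates from v*T1 = {rhs:.6g}"
            )

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.as_dict(),
            "noise": self.noise.as_dict(),
            "grid": None if self.grid is None else
                {"period": self.grid.period, "enabled": self.grid.enabled},
            "target": asdict(self.target),
            "achieved": self.achieved,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_deterministic(t1: float, v: float, free_param: str = "A",
                      fixed_value: float = 30.0) -> ModelParams:
    """Solve A*tau = v*T1 for the free deterministic parameter.

    ``free_param="A"`` solves A = v*T1/tau with tau fixed at ``fixed_value``
    (ms); ``free_param="tau"`` solves tau = v*T1/A with A fixed (volts).
    gamma is set to A/2. Warns when the exponential-rule deterministic ISI
    tau*ln((v - gamma + A)/(v - gamma)) deviates from T1 by more than 5%
    (the linearization is then questionable at this rate).
    """
    if t1 <= 0 or v <= 0 or fixed_value <= 0:
        raise ParameterError("T1, v and the fixed parameter must all be > 0")
    if free_param == "A":
        tau = fixed_value
        A = v * t1 / tau
    elif free_param == "tau":
        A = fixed_value
        tau = v * t1 / A
    else:
        raise ParameterError(f"free_param must be 'A' or 'tau', got {free_param!r}")
    params = ModelParams(v=v, A=A, tau=tau)
    if abs(params.isi_exponential - t1) > 0.05 * t1:
        warnings.warn(
            f"exponential-rule deterministic ISI {params.isi_exponential:.4g} ms "
            f"deviates from target T1 = {t1:.4g} ms by more than 5%"
        )
    return params


def fit_noise(sccs: SCCSequence, v: float = DEFAULT_V,
              snr_db: float | None = None, r0: float | None = None) -> ARNoiseSpec:
    """AR(1) noise spec from observed SCCs.

    The pattern fixes the coefficient sign; the magnitude comes from the lag
    ratio rho_2/rho_1 when defined, falling back to the lag-1 inversion.
    Power comes from ``r0`` directly or from ``snr_db`` via
    R0 = v^2 10^(-SNR/10) (default 30 dB). OTHER patterns are unfittable.
    """
    pattern = classify_pattern(sccs)
    if pattern is PatternLabel.OTHER:
        raise UnfittablePatternError(
            f"SCC pattern {pattern.value} is outside the AR(1) families "
            f"(rho_1 = {sccs.rho[1]:.3f}, rho_2 = {sccs.rho[2]:.3f})"
        )
    if r0 is None:
        r0 = snr_to_power(30.0 if snr_db is None else snr_db, v)
    if pattern is PatternLabel.TYPE_III:
        return ARNoiseSpec(a=0.0, sign=0, r0=r0)
    try:
        a, clipped = estimate_a(sccs, method="ratio", pattern=pattern)
    except (ParameterError, UnfittablePatternError):
        a, clipped = estimate_a(sccs, method="rho1", pattern=pattern)
    if clipped or a == 0.0:
        a, _ = estimate_a(sccs, method="rho1", pattern=pattern)
    sign = +1 if pattern is PatternLabel.TYPE_I else -1
    if a == 0.0:
        return ARNoiseSpec(a=0.0, sign=0, r0=r0)
    return ARNoiseSpec(a=a, sign=sign, r0=r0)


def _achieved_stats(isis, cfg: SCCEstimatorConfig) -> dict:
    est = estimate_sccs(isis, cfg)
    return {
        "t1": float(np.mean(isis.intervals)),
        "cv": float(np.std(isis.intervals) / np.mean(isis.intervals)),
        "rho1": float(est.rho[1]),
        "rho2": float(est.rho[2]),
        "scc_sum": float(np.sum(est.rho[1:])),
        "sccs": est.rho.tolist(),
    }


def match_and_verify(
    target: TargetStats,
    sim_length: int = 200_000,
    seed: int = 0,
    v: float = DEFAULT_V,
    tau: float = 30.0,
    max_iter: int = 20,
    rho_tol: float = 0.02,
    cv_tol: float = 0.05,
) -> MatchedModel:
    """Fit, simulate, and iteratively re-tune a matched model.

    Deterministic constants come from :func:`fit_deterministic` (tau fixed);
    the initial noise magnitude from the target (rho_1, rho_2) and the
    initial power from the CV through the linearized variance relation
    Var(ISI) = 2 (R0 - R1)/m^2. Each iteration simulates ``sim_length``
    intervals with the exponential rule (on the target's EOD grid when one
    is given), re-estimates (rho_1, CV), then takes a secant step on the
    noise magnitude ``a`` (bounded to (0, 0.98]) against the rho_1 mismatch
    and rescales R0 multiplicatively against the CV mismatch. Returns the
    best candidate, flagged non-converged if the caps are exhausted.
    """
    params = fit_deterministic(target.t1, v, free_param="A", fixed_value=tau)
    target_sccs = SCCSequence(np.array([1.0, target.rho1, target.rho2]),
                              kind="estimated")
    m = params.m
    var_target = (target.cv * target.t1) ** 2

    spec = fit_noise(target_sccs, v=v, r0=1.0)  # sign and initial a; r0 replaced below
    s_coeff = spec.sign * spec.a
    r0 = var_target * m**2 / (2.0 * (1.0 - s_coeff)) if s_coeff != 1.0 else var_target * m**2
    spec = ARNoiseSpec(a=spec.a, sign=spec.sign, r0=r0)
    grid = EODGrid(period=target.eod_period) if target.eod_period else None

    cfg = SCCEstimatorConfig(block_size=min(2000, max(100, sim_length // 10)))
    unit_scale = target.eod_period if grid is not None else 1.0

    history: list[tuple[float, float]] = []  # (a, rho1_achieved)
    best = None
    best_err = np.inf
    achieved = {}
    it = 0
    for it in range(1, max_iter + 1):
        isis = simulate_isis(params, spec, sim_length, seed=seed + it, grid=grid)
        achieved = _achieved_stats(isis, cfg)
        achieved["t1_ms"] = achieved["t1"] * unit_scale
        err = abs(achieved["rho1"] - target.rho1)
        cv_err = abs(achieved["cv"] / target.cv - 1.0) if target.cv > 0 else 0.0
        if err < best_err:
            best_err = err
            best = (spec, achieved)
        if err <= rho_tol and cv_err <= cv_tol:
            return MatchedModel(params=params, noise=spec, grid=grid, target=target,
                               achieved=achieved, converged=True, n_iter=it, seed=seed)
        # R0 update: CV matching adjusts power only, never a
        new_r0 = spec.r0 * (target.cv / achieved["cv"]) ** 2 if achieved["cv"] > 0 else spec.r0
        # a update: secant on f(a) = rho1_achieved(a) - rho1_target
        new_a = spec.a
        if spec.sign != 0:
            history.append((spec.a, achieved["rho1"]))
            if len(history) >= 2 and history[-1][1] != history[-2][1]:
                (a0, f0), (a1, f1) = history[-2], history[-1]
                slope = (f1 - f0) / (a1 - a0) if a1 != a0 else 0.0
                if slope != 0.0:
                    new_a = a1 - (f1 - target.rho1) / slope
                else:
                    new_a = a1 * (1.1 if (target.rho1 - f1) * spec.sign > 0 else 0.9)
            else:
                # first multiplicative probe in the direction of the mismatch
                mismatch = target.rho1 - achieved["rho1"]
                step = 1.0 + 0.5 * np.sign(mismatch) * spec.sign
                new_a = spec.a * max(step, 0.1)
            new_a = float(np.clip(new_a, 1e-4, 0.98))
        spec = ARNoiseSpec(a=new_a, sign=spec.sign, r0=float(new_r0))

    spec, achieved = best
    return MatchedModel(params=params, noise=spec, grid=grid, target=target,
                       achieved=achieved, converged=False, n_iter=it, seed=seed)
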