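"""Synthetic test-input generator.

Produces spike trains emulating the study conditions under which the model
families were matched to P-type electrosensory afferents: high firing rates
(~150-400 spikes/s), at most one spike per electric-organ-discharge (EOD)
cycle with EOD periods near 1 ms, unimodal (non-bursting) and bimodal
(bursting) ISI distributions, and the three serial-correlation patterns. The
parameter sets for the correlated kinds are the published matched-model
configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .model import EODGrid, ISISequence, ModelParams, SpikeTrain, simulate_isis
from .noise import ARNoiseSpec
from . import io as dio

__all__ = ["FIXTURE_KINDS", "FixtureBundle", "generate_fixtures"]

# kind -> (ModelParams kwargs, ARNoiseSpec kwargs, EOD period in ms)
FIXTURE_KINDS = {
    # Type I (non-bursting, unimodal): matched non-bursting afferent config
    "type1": (dict(v=1.845, A=0.15, tau=30.0),
              dict(a=0.4, sign=+1, r0=1.07e-3), 1.06),
    # Type II, moderate bursting
    "type2_moderate": (dict(v=1.845, A=0.28, tau=26.0),
                       dict(a=0.29, sign=-1, r0=9.22e-3), 1.31),
    # Type II, strong bursting (bimodal, mode near one EOD cycle)
    "type2_strong": (dict(v=1.845, A=0.19, tau=60.0),
                     dict(a=0.69, sign=-1, r0=6.4e-3), 1.04),
    # Type III: white threshold noise, no grid so rho_1 = -1/2 is undistorted.
    # Weaker power (SNR 50 dB) keeps the linearized rule inside its validity
    # domain (threshold excursions well below the jump A); the SCC pattern is
    # invariant to the power.
    "type3": (dict(v=1.845, A=0.15, tau=30.0),
              dict(a=0.0, sign=0, r0=3.404e-5), None),
    # renewal surrogate: type3 intervals randomly permuted
    "renewal": (dict(v=1.845, A=0.15, tau=30.0),
                dict(a=0.0, sign=0, r0=3.404e-5), None),
}


@dataclass
class FixtureBundle:
    kind: str
    train: SpikeTrain
    isis: ISISequence
    manifest: dict
    paths: dict | None = None


def generate_fixtures(kind: str, n_spikes: int = 20_000, seed: int = 0,
                      outdir=None) -> FixtureBundle:
    """Simulate one fixture kind; optionally write its files.

    Emits (when ``outdir`` is given) the spike-time file, the ISI file and a
    JSON manifest with the generating parameters and seed. The ``renewal``
    kind shuffles the white-noise train's intervals, which preserves the ISI
    distribution but destroys every serial correlation.
    """
    if kind not in FIXTURE_KINDS:
        raise ParameterError(
            f"unknown fixture kind {kind!r}; choose from {sorted(FIXTURE_KINDS)}"
        )
    pkw, nkw, eod = FIXTURE_KINDS[kind]
    params = ModelParams(**pkw)
    spec = ARNoiseSpec(**nkw)
    grid = EODGrid(period=eod) if eod else None
    # off-grid kinds use the linearized rule, for which white threshold noise
    # yields the exact degenerate pattern (rho_1 = -1/2, rest 0)
    rule = "exponential" if grid else "linearized"
    isis = simulate_isis(params, spec, n_spikes - 1, seed=seed, grid=grid, rule=rule)
    if kind == "renewal":
        rng = np.random.default_rng(seed + 1)
        isis = ISISequence(rng.permutation(isis.intervals), unit=isis.unit,
                           meta=dict(isis.meta, shuffled=True))
    scale = eod if (grid is not None and isis.unit == "eod") else 1.0
    times = np.concatenate([[0.0], np.cumsum(isis.intervals * scale)])
    train = SpikeTrain(times,
                       time_base="eod_grid" if grid else "continuous",
                       eod_period=eod,
                       meta={"kind": kind, "seed": seed})
    manifest = {
        "kind": kind,
        "seed": seed,
        "n_spikes": int(times.size),
        "params": params.as_dict(),
        "noise": spec.as_dict(),
        "eod_period": eod,
    }
    paths = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "spikes": outdir / f"{kind}_spikes.txt",
            "isis": outdir / f"{kind}_isis.txt",
            "manifest": outdir / f"{kind}_manifest.json",
        }
        dio.write_spike_times(train, paths["spikes"])
        dio.write_isis(isis, paths["isis"])
        paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return FixtureBundle(kind=kind, train=train, isis=isis,
                         manifest=manifest, paths=paths)
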