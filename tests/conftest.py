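import numpy as np
import pytest

from dynthresh import ARNoiseSpec, ModelParams


@pytest.fixture
def fig6_params() -> ModelParams:
    """Published matched Type I encoder constants."""
    return ModelParams(v=1.845, A=0.15, tau=30.0)


@pytest.fixture
def type1_spec() -> ARNoiseSpec:
    return ARNoiseSpec(a=0.4, sign=+1, r0=1.07e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_psd_acf(rng: np.random.Generator, K: int, n_comp: int = 5) -> np.ndarray:
    """A valid (positive semidefinite) autocorrelation sequence.

    Superposition of cosines with nonnegative weights: a discrete spectral
    measure, hence PSD by Bochner's theorem, with a touch of white noise to
    keep the Toeplitz matrix well conditioned.
    """
    weights = rng.uniform(0.1, 1.0, size=n_comp)
    freqs = rng.uniform(0.0, np.pi, size=n_comp)
    k = np.arange(K + 1)
    r = (weights[:, None] * np.cos(freqs[:, None] * k[None, :])).sum(axis=0)
    r[0] += 0.25 * weights.sum()  # white-noise floor
    return r
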