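import numpy as np
import pytest

from spikeglm.data import SpikeCountMatrix
from spikeglm.params import ModelParams, default_params


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_params(variant: str, n_neurons: int, rng: np.random.Generator,
                  dt: float = 0.01) -> ModelParams:
    """A random, moderately-scaled parameter set honoring variant
    constraints (diagonal zeroing happens in the constructor)."""
    p = default_params(variant, n_neurons, dt=dt)
    return ModelParams(
        variant=variant,
        weights=rng.normal(0.0, 0.3, p.weights.shape),
        diag_weights=rng.normal(0.0, 0.3, p.diag_weights.shape),
        h=rng.normal(-1.0, 0.5, n_neurons),
        g_sfa=np.abs(rng.normal(0.5, 0.2, 5)),
        tau_sfa=p.tau_sfa,
        lambda_inf=2.0, gamma=1.3, r_nb=0.22, dt=dt,
    )


def random_counts(n_neurons: int, n_bins: int, rng: np.random.Generator,
                  rate: float = 0.3, dt: float = 0.01) -> SpikeCountMatrix:
    return SpikeCountMatrix(rng.poisson(rate, size=(n_neurons, n_bins)), dt=dt)


@pytest.fixture(scope="session")
def small_ground_truth():
    """A planted bursting network shared across tests (N=8, short probe)."""
    from spikeglm.synth import SynthConfig, make_ground_truth
    cfg = SynthConfig(n_neurons=8, probe_bins=15_000)
    params, layout = make_ground_truth(cfg, np.random.default_rng(5))
    return cfg, params, layout


@pytest.fixture(scope="session")
def small_dataset(small_ground_truth):
    from spikeglm.synth import generate_dataset
    _, params, _ = small_ground_truth
    counts, table = generate_dataset(params, 30_000, np.random.default_rng(5))
    return counts, table
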