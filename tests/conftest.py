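import numpy as np
import pytest

from pupilgca.design import Ar1Noise, ArtifactRates, DesignSpec

NO_NOISE = dict(rho=0.99, sd_mm=0.0, trial_sd_mm=0.0)
NO_ARTIFACTS = dict(blink_rate_per_s=0.0, spike_rate_per_s=0.0, dropout_prob=0.0)


def degenerate_spec(**overrides) -> DesignSpec:
    """Zero-noise, zero-artifact, zero-random-effect spec (exactness checks)."""
    kwargs = dict(
        n_participants=3,
        n_items_per_cell=2,
        n_fillers=4,
        random_sd={k: 0.0 for k in DesignSpec.RANDOM_TERMS},
        noise=Ar1Noise(**NO_NOISE),
        artifact_rates=ArtifactRates(**NO_ARTIFACTS),
        seed=7,
    )
    kwargs.update(overrides)
    return DesignSpec(**kwargs)


def clean_spec(**overrides) -> DesignSpec:
    """No noise or artifacts, but participant random effects present."""
    kwargs = dict(
        n_participants=4,
        n_items_per_cell=3,
        n_fillers=4,
        noise=Ar1Noise(**NO_NOISE),
        artifact_rates=ArtifactRates(**NO_ARTIFACTS),
        seed=11,
    )
    kwargs.update(overrides)
    return DesignSpec(**kwargs)


@pytest.fixture(scope="session")
def degenerate_experiment():
    from pupilgca.simulate import simulate_dataset

    return simulate_dataset(degenerate_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
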