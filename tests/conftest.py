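import numpy as np
import pytest

from vidradiomics import pipeline, synthvideo


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort: planted signals are exactly recoverable."""
    cfg = synthvideo.SynthConfig(
        n_cases=6,
        positive_fraction=0.5,
        frame_count=16,
        frame_shape=(96, 96),
        noise_sigma=0.0,
        seed=5,
    )
    return synthvideo.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def noisy_cohort_small():
    """Small cohort at default (moderate) speckle noise."""
    cfg = synthvideo.SynthConfig(
        n_cases=12,
        positive_fraction=0.5,
        frame_count=16,
        frame_shape=(96, 96),
        seed=7,
    )
    return synthvideo.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def cohort200_features():
    """Default-condition 200-case cohort, fully featurized once per session.

    Default generator conditions: class temporal frequencies 0.05 vs 0.20
    cycles/frame, moderate speckle noise, class-shifted clinical covariates.
    """
    cfg = synthvideo.SynthConfig(n_cases=200, seed=0)
    cases = synthvideo.generate_cohort(cfg)
    return pipeline.cohort_features(cases)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
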