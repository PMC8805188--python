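import numpy as np
import pytest

from rhi_mvpa import EffectSpec, EpochedDataset, StudyConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """Reduced study: 16 channels, 2 conditions, 2 short trials each."""
    return StudyConfig(
        n_participants=3,
        n_channels=16,
        conditions=("IllusionNext", "IncongruentNext"),
        trials_per_condition=2,
        events_per_trial=40,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Generated small study with one injected illusion effect."""
    effects = [EffectSpec(id="ill", contrast=("IllusionNext", "IncongruentNext"),
                          window=(0.08, 0.30), amplitude=6.0)]
    return generate_dataset(small_config, effects,
                            onset_kwargs={"median_next": 12, "median_under": 10})


def make_epochs(
    n_epochs=20, n_channels=4, n_samples=161, fs=200.0, rng=None,
    condition="IllusionNext", participant="P01", event_times=None, trial_index=None,
    data=None,
) -> EpochedDataset:
    """Hand-built epoch container for unit tests."""
    rng = rng or np.random.default_rng(0)
    if data is None:
        data = rng.standard_normal((n_epochs, n_channels, n_samples))
    n_epochs = data.shape[0]
    times = (np.arange(n_samples) - (n_samples - 1) / 2) / fs
    return EpochedDataset(
        data=data,
        times=times,
        fs=fs,
        condition=condition,
        participant=participant,
        event_times=np.arange(n_epochs, dtype=float) if event_times is None else np.asarray(event_times, float),
        trial_index=np.zeros(n_epochs, int) if trial_index is None else np.asarray(trial_index, int),
    )
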