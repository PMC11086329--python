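import numpy as np
import pytest

from ppgrehab.synth import SynthConfig, generate_dataset


@pytest.fixture
def quiet_config():
    """Noise-free single-subject generator configuration (healthy stage)."""
    def make(stage="VII", duration_s=60.0, hr_bpm=60.0, jitter=0.0,
             spo2=97.0, seed=1, **kwargs):
        counts = {"V": 0, "VI": 0, "VII": 0}
        counts[stage] = 1
        return SynthConfig(
            subjects_per_class=counts, duration_s=duration_s,
            hr_mean_bpm=hr_bpm, hr_sd_bpm=0.0, hrv_jitter_frac=jitter,
            target_spo2_pct=spo2, spo2_sd_pct=0.0,
            noise_random_sd=0.0, drift_amp=0.0, spike_rate_per_s=0.0,
            mains_amp=0.0, seed=seed, **kwargs,
        )
    return make


@pytest.fixture
def quiet_record(quiet_config):
    def make(**kwargs):
        return generate_dataset(quiet_config(**kwargs))[0]
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
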