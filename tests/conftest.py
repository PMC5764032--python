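import numpy as np
import pytest

import ftcdlat as f


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def make_recording(
    d: float = 3.0,
    n_trials: int = 20,
    pulsatility: float = 12.0,
    noise_pct: float = 0.0,
    trial_sd: float = 0.0,
    seed: int = 0,
    child_id: str = "c0",
    fs: float = 25.0,
    base_left: float = 60.0,
    base_right: float = 55.0,
    offsets: tuple[float, float] | None = None,
    activation_pct: float = 4.0,
    validity: np.ndarray | None = None,
) -> f.RawRecording:
    """One synthetic recording with a known injected lateral effect ``d``."""
    rng = np.random.default_rng(seed)
    if offsets is None:
        left_off, right_off = d / 2.0, -d / 2.0
    else:
        left_off, right_off = offsets
    trial_d = rng.normal(0.0, trial_sd, n_trials) if trial_sd > 0 else np.zeros(n_trials)
    return f.synthesize_recording(
        child_id,
        sampling_rate=fs,
        n_trials=n_trials,
        base_left=base_left,
        base_right=base_right,
        pulsatility_amplitude=pulsatility,
        heart_rate=90.0,
        heart_phase=0.3,
        activation_peak_pct=activation_pct,
        poi_offsets_left=np.full(n_trials, left_off) + trial_d / 2.0,
        poi_offsets_right=np.full(n_trials, right_off) - trial_d / 2.0,
        signal_noise_pct=noise_pct,
        trial_validity=np.ones(n_trials, dtype=bool) if validity is None else validity,
        word_counts=np.full(n_trials, 20),
        rng=rng,
    )


@pytest.fixture(scope="session")
def clean_recording():
    """Pulsatile, noise-free recording with injected effect 3."""
    return make_recording(d=3.0)


@pytest.fixture(scope="session")
def noisefree_config():
    """Generator configuration with every noise source disabled, injected LI 3."""
    return f.SimulationConfig(
        n_pairs=2, artefact_rate=0.0, dropout_rate=0.0, invalid_trial_rate=0.0,
        pulsatility_amplitude=0.0, lateral_effect_sd=0.0, lateral_effect_mean=3.0,
        signal_noise_pct=0.0, trial_effect_sd=0.0, seed=1,
    )
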