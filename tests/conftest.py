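import numpy as np
import pandas as pd
import pytest

from pacpredict import PacSpec, SyntheticConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_recording():
    """A cheap 2-channel recording with one seizure for IO/pipeline tests."""
    cfg = SyntheticConfig(
        fs=128,
        n_channels=2,
        duration=600,
        seizure_onsets=[400],
        interictal_pac=PacSpec(f_phase=6, f_amp=45, chi=0.05),
        preictal_pac=PacSpec(f_phase=6, f_amp=45, chi=0.8),
        noise_sd=0.3,
        seed=7,
        sph_min=0.5,
        preictal_min=2.0,
        ictal_duration_s=20.0,
    )
    return generate_recording(cfg)


def make_gaussian_feature_table(
    n_seizures=10,
    windows_per_class=20,
    channels=("CH01",),
    pre_mean=0.4,
    pre_sd=0.05,
    inter_mean=0.05,
    inter_sd=0.02,
    seed=0,
):
    """Feature table with a known class separation, bypassing signal synthesis."""
    rng = np.random.default_rng(seed)
    rows = []
    start = 0.0
    for sid in range(n_seizures):
        for ch in channels:
            for label, mu, sd in (
                ("preictal", pre_mean, pre_sd),
                ("interictal", inter_mean, inter_sd),
            ):
                for _ in range(windows_per_class):
                    rows.append(
                        {
                            "channel": ch,
                            "window_start": start,
                            "label": label,
                            "seizure_id": sid,
                            "mi_beta_gamma": rng.normal(mu, sd),
                        }
                    )
                    start += 15.0
    return pd.DataFrame(rows)
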