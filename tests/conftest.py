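import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kneeload.synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    return syn.sample_cohort(6, 3)


@pytest.fixture(scope="session")
def profile(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def clean_load_model():
    """Generative load model without peak noise or share jitter."""
    return syn.GenerativeLoadModel(peak_noise_sd=0.0, medial_share_jitter=0.0)


@pytest.fixture(scope="session")
def trial_noisefree(profile, clean_load_model):
    return syn.make_trial(
        profile, "comfortable", "right", seed=42, load_model=clean_load_model
    )


@pytest.fixture(scope="session")
def trial_noisy(profile):
    return syn.make_trial(
        profile, "comfortable", "left", seed=43, noise=syn.NOISE_REALISTIC
    )


@pytest.fixture(scope="session")
def linear_training_table(clean_load_model):
    """Noiseless predictor/peak pairs generated by the linear load model."""
    subjects = syn.sample_cohort(120, 5)
    return syn.generate_training_table(
        subjects, 6, seed=9, load_model=clean_load_model
    )


def brute_force_peaks(raw: np.ndarray) -> tuple[float, float, float]:
    """Independent reference implementation of the half-window peak rule,
    written as explicit loops over the samples."""
    n = len(raw)
    padded = np.concatenate([[raw[0]] * 2, raw, [[raw[-1]][0]] * 2])
    smooth = np.array(
        [np.mean(padded[i : i + 5]) for i in range(n)]
    )
    mid = n // 2

    def half(lo, hi):
        best_i, best_s = None, -np.inf
        for i in range(max(lo, 1), min(hi, n - 1)):
            if smooth[i] > smooth[i - 1] and smooth[i] > smooth[i + 1]:
                if smooth[i] > best_s:
                    best_i, best_s = i, smooth[i]
        if best_i is None:
            return max(raw[lo:hi])
        return raw[best_i]

    lr = float(half(0, mid))
    te = float(half(mid, n))
    return lr, te, max(lr, te)
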