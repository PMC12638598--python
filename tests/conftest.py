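import numpy as np
import pytest

from pataka import SyllableTrainSpec, synthesize_ddk_recording
from pataka.preprocess import preprocess_recording


@pytest.fixture(scope="session")
def standard_train():
    """A clean 40-repetition train with known timing (seeded)."""
    spec = SyllableTrainSpec(
        sample_rate=16000, n_repetitions=40, ioi_mean=0.25, ioi_sd=0.01,
        syllable_duration=0.13, vot=0.040, snr_db=30, seed=11,
    )
    rec, manifest = synthesize_ddk_recording(spec)
    return spec, rec, manifest


@pytest.fixture(scope="session")
def standard_train_clean(standard_train):
    spec, rec, manifest = standard_train
    return spec, preprocess_recording(rec), manifest


def match_onsets(detected: np.ndarray, truth: np.ndarray, tol: float = 0.05):
    """Greedy one-to-one matching of detected to true onsets within tol."""
    used = np.zeros(len(detected), dtype=bool)
    matches = []
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] < tol:
            used[j] = True
            matches.append((j, t))
    return matches
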