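import numpy as np
import pytest

from melodic_trf.layout import make_layout
from melodic_trf.synth import (
    CohortSpec,
    MarkovMelodyModel,
    NoteSequence,
    analytic_information,
    default_kernels,
    generate_melody,
)
from melodic_trf.features import build_feature_matrix
from melodic_trf.trf import LagWindow


@pytest.fixture(scope="session")
def order1_model() -> MarkovMelodyModel:
    """Small fully specified first-order model for exact-value checks."""
    alphabet = [60, 62, 64]
    trans = {
        (60,): np.array([0.5, 0.25, 0.25]),
        (62,): np.array([0.8, 0.2, 0.0]),
        (64,): np.array([1.0 / 3, 1.0 / 3, 1.0 / 3]),
    }
    return MarkovMelodyModel(
        pitch_alphabet=alphabet,
        pitch_transition=trans,
        pitch_initial=np.array([0.25, 0.5, 0.25]),
        ioi_values=np.array([0.25, 0.5]),
        ioi_transition=np.array([[0.8, 0.2], [0.4, 0.6]]),
        ioi_initial=np.array([0.5, 0.5]),
        order=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def random_model() -> MarkovMelodyModel:
    return MarkovMelodyModel.random(seed=11)


@pytest.fixture(scope="session")
def short_melody(random_model):
    return generate_melody(random_model, 20.0, seed=5)


@pytest.fixture(scope="session")
def short_features(random_model, short_melody):
    info = analytic_information(random_model, short_melody)
    return build_feature_matrix(short_melody, info, 64.0)


@pytest.fixture(scope="session")
def lag_window() -> LagWindow:
    return LagWindow(-150.0, 750.0, 64.0)


@pytest.fixture(scope="session")
def small_cohort() -> CohortSpec:
    return CohortSpec(
        n_subjects=2,
        n_melodies=2,
        n_repeats=2,
        melody_length_s=20.0,
        n_channels=8,
        fs_eeg=64.0,
        fs_analysis=64.0,
        snr=10.0,
        seed=21,
    )


@pytest.fixture(scope="session")
def layout16():
    return make_layout(16)


@pytest.fixture
def three_notes() -> NoteSequence:
    return NoteSequence(
        onsets=np.array([0.5, 1.0, 1.75]),
        pitches=np.array([60, 64, 62]),
        durations=np.array([0.4, 0.6, 0.2]),
        duration_total=2.5,
    )
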