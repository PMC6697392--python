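import numpy as np
import pytest

from uvalley import design


@pytest.fixture(scope="session")
def stimuli():
    return design.build_stimulus_set()


@pytest.fixture(scope="session")
def rating_trials(stimuli):
    return design.build_rating_trials(stimuli, repetitions=2, seed=11)


@pytest.fixture(scope="session")
def choice_design(stimuli):
    return design.build_choice_design(stimuli, trials_per_contrast=12, seed=11)


@pytest.fixture(scope="session")
def category_axes():
    """(latent humanlikeness, is_human, names) for the six categories."""
    cats = design.DEFAULT_CATEGORIES
    return (np.array([c.latent_humanlikeness for c in cats]),
            np.array([c.is_human for c in cats]),
            [c.name for c in cats])


@pytest.fixture()
def default_params():
    return design.SubjectParams()


@pytest.fixture()
def noiseless_params():
    return design.SubjectParams(rating_noise_sd=0.0, amplitude_noise_sd=0.0,
                                confidence_noise_sd=0.0)


@pytest.fixture(scope="session")
def subject_data():
    return design.simulate_subject(design.SubjectParams(), seed=21)
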