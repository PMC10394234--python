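import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from mmnpipe.cohort import default_study_design
from mmnpipe.forward import HeadModel
from mmnpipe.inverse import build_source_model
from mmnpipe.montage import build_montage
from mmnpipe.paradigm import generate_sequence

#: master seed of the cohort-level simulations in this suite
SUITE_SEED = 7


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def source_model(montage, head):
    return build_source_model(montage, head)


@pytest.fixture(scope="session")
def sequence():
    return generate_sequence(SUITE_SEED)


@pytest.fixture(scope="session")
def design():
    return default_study_design(SUITE_SEED)


@pytest.fixture(scope="session")
def cohort_table(design, montage, head):
    """Full default-cohort simulation and analysis (the expensive path).

    Session-scoped: the group-separation and recovery checks share one
    run of the 211-subject pipeline.
    """
    from mmnpipe.pipeline import run_cohort_analysis

    return run_cohort_analysis(design, montage, head)


def canonical_profile(amps=(14.71, 13.08, 13.95), latency_ms=200.0,
                      noise_rms_uv=0.0, blink_rate_hz=0.0):
    """A control subject at the published group-mean source amplitudes,
    identical across deviant conditions (no cross-condition leakage)."""
    from mmnpipe.cohort import SubjectProfile

    amps = np.asarray(amps, float)
    return SubjectProfile(
        subject_id="canon",
        group="CON",
        transition=False,
        source_mmn_amp={k: amps.copy() for k in
                        ("duration", "frequency", "intensity")},
        mmn_peak_latency_ms=latency_ms,
        standard_response_amp=20.0,
        noise_rms_uv=noise_rms_uv,
        blink_rate_hz=blink_rate_hz,
        age=21.0, sex="F", sips_pos=0.0, sips_neg=0.0, gaf=85.0,
        seed=99,
    )


@pytest.fixture(scope="session")
def noiseless_subject(montage, head, sequence):
    """One noiseless, blink-free simulated control subject plus its
    generative profile (shared by calibration-identity checks)."""
    from mmnpipe.cohort import simulate_subject

    profile = canonical_profile()
    raw = simulate_subject(profile, sequence, montage, head)
    return profile, raw
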