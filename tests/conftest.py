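import numpy as np
import pytest

import confusim as cf


@pytest.fixture(scope="session")
def default_design():
    """One replicate of the full 24-subject factorial design (1512 rows)."""
    return cf.build_design(replicates=1)


@pytest.fixture(scope="session")
def default_responses(default_design):
    """Synthetic responses under the default psychometric truth."""
    return cf.generate_responses(default_design, cf.PsychometricParams(), rng_seed=42)


@pytest.fixture(scope="session")
def default_ladder(default_design):
    """Model ladder fitted on a two-replicate design (shared: it is the
    most expensive fit in the suite)."""
    from confusim import analysis_pipeline as ap

    design = cf.build_design(replicates=2)
    responses = cf.generate_responses(design, cf.PsychometricParams(), rng_seed=0)
    return ap.model_ladder(responses)


@pytest.fixture()
def short_motion_params():
    """A 5-frame trial for rendering tests."""
    return cf.MotionParams(sigma=np.pi / 16, highlight_duration=20.0, track_duration=30.0)
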