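import numpy as np
import pytest
from scipy.special import logit

from rangehab import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def default_survey():
    """One default-design survey (41 sites, 349 point counts), seed fixed."""
    cfg = SurveyConfig(seed=42)
    points, truth = generate_survey(cfg)
    return cfg, points, truth


@pytest.fixture(scope="session")
def survey_data(default_survey):
    """Survey table with the true detectability offset attached."""
    _, points, truth = default_survey
    return points.assign(
        p_detect=truth.detection_prob,
        logit_p_detect=logit(np.clip(truth.detection_prob, 1e-12, 1 - 1e-12)),
    )
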