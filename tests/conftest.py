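"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from mlipop import dff as dffm
from mlipop import synth
from mlipop.config import (EnsembleConfig, LearningCurve, PeriodWindows,
                           SessionConfig)


@pytest.fixture(scope="session")
def proficient_session():
    """100-trial session from an animal proficient throughout."""
    cfg = SessionConfig(n_trials=100, seed=11)
    lc = LearningCurve(start_pc=85.0, asymptote_pc=95.0, inflection_trial=0,
                       slope=1.0)
    return synth.generate_session(cfg, EnsembleConfig(), lc)


@pytest.fixture(scope="session")
def learning_session():
    """120-trial session crossing naive to proficient."""
    cfg = SessionConfig(n_trials=120, seed=5)
    return synth.generate_session(cfg, EnsembleConfig(),
                                  LearningCurve(inflection_trial=40))


@pytest.fixture(scope="session")
def proficient_dff(proficient_session):
    s = proficient_session
    return dffm.compute_dff(s.F, [t.t_start for t in s.trials],
                            s.imaging_rate)


@pytest.fixture(scope="session")
def odor_tensor(proficient_session, proficient_dff):
    return dffm.align_trials(proficient_dff, proficient_session.trials,
                             "odor_on", (-10.0, 6.0),
                             proficient_session.imaging_rate)


@pytest.fixture(scope="session")
def windows():
    return PeriodWindows()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
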