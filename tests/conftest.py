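import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pausekit.synthetic import PauseSiteParams, TemplateSpec
from pausekit.traces import StepPath


@pytest.fixture
def single_pause_template():
    """Short template with one pause site of efficiency 0.427 at bp 34."""
    kn = 0.5
    e = 0.427
    kp = kn * e / (1.0 - e)
    return TemplateSpec(
        length=40, kn=kn,
        pause_sites={34: PauseSiteParams(kp=kp, k_escape=1.0 / 126.0)})


def make_step_path(positions, dwells, t0=0.0):
    """StepPath from per-position dwell times (s)."""
    dwells = np.asarray(dwells, dtype=float)
    starts = t0 + np.concatenate([[0.0], np.cumsum(dwells[:-1])])
    return StepPath(position_bp=np.asarray(positions),
                    t_start=starts, t_end=starts + dwells)


@pytest.fixture
def step_path_factory():
    return make_step_path
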