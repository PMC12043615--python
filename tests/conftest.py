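import warnings

import pytest

from metpower import synth
from metpower.types import AthleteProfile

# the maximal protocols intentionally push a few samples past the fitted
# equivalent-slope range; keep that warning out of the test logs
warnings.filterwarnings("ignore", message=".*equivalent-slope range.*")


@pytest.fixture(scope="session")
def athlete() -> AthleteProfile:
    """Cohort-mean athlete: 81.2 kg, VO2max 64.8 ml/kg/min."""
    return AthleteProfile(mass=81.2, vo2max=64.8)


@pytest.fixture(scope="session")
def zero_noise_sessions(athlete):
    """One noiseless synthetic session per protocol, truth attached."""
    out = {}
    for name in ("continuous_shuttles", "repeated_accelerations",
                 "repeated_sprints"):
        kin = synth.default_kinetics(name).noiseless()
        out[name] = synth.generate_session(name, athlete, kin, seed=11)
    return out
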