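import numpy as np
import pytest

from pupilprep import FilterSettings, ProcessingSettings, SyntheticScenario, generate


@pytest.fixture
def fsettings():
    return FilterSettings()


@pytest.fixture
def psettings():
    return ProcessingSettings()


@pytest.fixture
def smooth_trace():
    """Artifact-free noisy slow sine at 100 Hz, 20 s."""
    rng = np.random.default_rng(42)
    t = np.arange(0, 20, 0.01)
    d = 4.5 + 0.4 * np.sin(2 * np.pi * 0.2 * t) + rng.normal(0, 0.02, t.size)
    return t, d


@pytest.fixture
def default_scenario_run():
    """One default synthetic scenario rendered with a fixed seed."""
    rec, ledger, truth = generate(SyntheticScenario(seed=7))
    return rec, ledger, truth
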