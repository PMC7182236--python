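import numpy as np
import pytest

from fpvs import ForwardModel, SimulationConfig, design


@pytest.fixture(scope="session")
def forward_model():
    return ForwardModel.default()


@pytest.fixture(scope="session")
def small_forward_model():
    """Reduced montage (16 occipito-parietal + frontal channels, 2 EOG) to
    keep simulation-heavy tests fast."""
    names = [
        "Oz", "O1", "O2", "POz", "PO3", "PO4", "PO7", "PO8",
        "Pz", "P1", "P2", "Cz", "Fz", "Fp1", "Fp2", "FCz",
        "EXG1", "EXG2",
    ]
    types = ["eeg"] * 16 + ["eog"] * 2
    return ForwardModel.default(names, types)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pilot1_small():
    """Pilot-1 design scaled to 10 trials per condition, no targets."""
    spec = design.scaled(design.preset("pilot1"), 10)
    import dataclasses

    return dataclasses.replace(spec, target_policy=None)


def quiet_sim_config(spec, **kw):
    return SimulationConfig.for_spec(spec, **kw)
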