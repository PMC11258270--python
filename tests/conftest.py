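import numpy as np
import pytest

from gluchip.io import default_params
from gluchip.model import Hypothesis, ModelParameters
from gluchip.protocol import SolverConfig, gtt_study_protocol


@pytest.fixture(scope="session")
def params_h1() -> ModelParameters:
    return default_params(Hypothesis.H1)


@pytest.fixture(scope="session")
def params_h2() -> ModelParameters:
    return default_params(Hypothesis.H2)


@pytest.fixture(scope="session")
def quick_solver() -> SolverConfig:
    """Loose-but-adequate tolerances for tests that only need qualitative
    trajectories."""
    return SolverConfig(rtol=1e-6, atol=(1e-10,) * 4 + (1e-6, 1e-6, 1e-15, 1e-4))


@pytest.fixture(scope="session")
def gtt_protocol():
    return gtt_study_protocol(11.0, gtt_days=(1, 7, 13))


def random_state(rng: np.random.Generator) -> np.ndarray:
    """A physically plausible random model state."""
    return np.array(
        [
            rng.uniform(0, 4e-3),  # NG liver (mmol)
            rng.uniform(0, 4e-3),  # NG pancreas
            rng.uniform(0, 2.0),  # NI liver (mIU)
            rng.uniform(0, 2.0),  # NI pancreas
            rng.uniform(0, 500.0),  # G_int
            rng.uniform(0, 12.0),  # G_slow
            rng.uniform(1e-10, 5e-8),  # V_beta
            rng.uniform(0, 400.0),  # t
        ]
    )


def random_params(rng: np.random.Generator, hypothesis) -> ModelParameters:
    """Random positive parameter draw around the defaults."""
    base = default_params(hypothesis)
    updates = {}
    for group in ("fast", "slow"):
        block = getattr(base, group)
        for name in vars(block):
            v = getattr(block, name)
            if name in ("I_max_Si",):
                updates[f"{group}.{name}"] = rng.uniform(0, 1)
            elif v > 0:
                updates[f"{group}.{name}"] = v * rng.uniform(0.3, 3.0)
    if hypothesis == Hypothesis.H2:
        updates["h2.I_max_additional"] = rng.uniform(0, 1)
        updates["h2.EC50_additional"] = rng.uniform(50, 500)
    updates["offsets.dG_d1"] = rng.normal(0, 0.5)
    updates["offsets.dI_d1"] = rng.uniform(0, 2.0)
    return base.set(updates)
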