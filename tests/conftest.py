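import numpy as np
import pytest

from twinsite.model import DIFF_KEYS, FreeEnergyParams, ModelClass


@pytest.fixture(scope="session")
def mc() -> ModelClass:
    return ModelClass()


@pytest.fixture(scope="session")
def mc_allosteric() -> ModelClass:
    return ModelClass(allostery=True)


def random_params(mc: ModelClass, seed: int, fast: bool = True) -> FreeEnergyParams:
    """A random free-energy parameter set (moderate barriers when fast)."""
    rng = np.random.default_rng(seed)
    lo, hi = (14.0, 30.0) if fast else (14.0, 43.0)
    barriers = {lab: rng.uniform(lo, hi) for lab in mc.labels}
    if mc.allostery:
        se = np.zeros(13)
        se[1:] = rng.uniform(-15.0, 10.0, size=12)
        return FreeEnergyParams(barriers=barriers, state_energies=se)
    diffs = {k: rng.uniform(-8.0, 2.0) for k in DIFF_KEYS}
    return FreeEnergyParams(barriers=barriers, diffs=diffs)


@pytest.fixture
def params(mc) -> FreeEnergyParams:
    return random_params(mc, seed=3)
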