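import numpy as np
import pytest
from hypothesis import settings

from optimmune.demography import build_leslie

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_leslie(rng: np.random.Generator, D: int | None = None) -> np.ndarray:
    """A random primitive Leslie matrix for eigen-machinery oracles."""
    if D is None:
        D = int(rng.integers(2, 9))
    fert = rng.uniform(0.1, 3.0, D)
    fert[: int(rng.integers(0, D // 2 + 1))] = 0.0
    if not np.any(fert > 0):
        fert[-1] = 1.0
    if fert[-1] == 0:
        fert[-1] = rng.uniform(0.1, 3.0)  # fertility in terminal class: irreducible
    surv = rng.uniform(0.2, 0.95, D)
    return build_leslie(fert, surv)
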