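import numpy as np
import pytest

from breathvar import ScenarioSpec, ParameterKind
from breathvar import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flat_matrix(parameter: str, true_sd: float, n_reps: int, seed: int,
                sighs=None, n_cycles: int = 300) -> np.ndarray:
    """Stack pre-trend replicates of one scenario as rows."""
    spec = ScenarioSpec(
        ParameterKind(parameter), true_sd=true_sd, sighs=sighs,
        n_cycles=n_cycles, n_reps=n_reps, seed=seed,
    )
    return np.vstack(
        [synthdata.base_replicate(spec, r).values for r in range(n_reps)]
    )
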