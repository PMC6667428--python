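import numpy as np
import pytest
from hypothesis import strategies as st

from pairsir import ModelParams, PairwiseState

# Standard illustration parameters: N=10,000, n=5, tau=gamma=1, phi=0.5.
FIG3 = dict(N=10_000.0, n=5.0, tau=1.0, gamma=1.0, phi=0.5)


@pytest.fixture
def fig3_params() -> ModelParams:
    return ModelParams(**FIG3)


@pytest.fixture
def unclustered_params() -> ModelParams:
    return ModelParams(**{**FIG3, "phi": 0.0})


@st.composite
def admissible_states(draw, n: float = 5.0, N: float = 10_000.0):
    """Random epidemic-like pairwise states obeying the stub bounds.

    Guarantees S, I > 0, S + I < N, SS + SI <= n S and II + SI <= n I, so the
    complementary R-class pair counts are non-negative too.
    """
    S = draw(st.floats(100.0, 8000.0, allow_nan=False))
    I = draw(st.floats(50.0, 1800.0, allow_nan=False))
    SI = draw(st.floats(1.0, 0.5 * n * min(S, I), allow_nan=False))
    SS = draw(st.floats(1.0, 0.9 * (n * S - SI), allow_nan=False))
    II = draw(st.floats(1.0, 0.9 * (n * I - SI), allow_nan=False))
    return PairwiseState(S=S, I=I, SI=SI, SS=SS, II=II)


def random_admissible_state(rng: np.random.Generator, n: float = 5.0, N: float = 10_000.0) -> PairwiseState:
    """Seeded counterpart of the hypothesis strategy for plain loops."""
    S = rng.uniform(100.0, 8000.0)
    I = rng.uniform(50.0, 1800.0)
    SI = rng.uniform(1.0, 0.5 * n * min(S, I))
    SS = rng.uniform(1.0, 0.9 * (n * S - SI))
    II = rng.uniform(1.0, 0.9 * (n * I - SI))
    return PairwiseState(S=S, I=I, SI=SI, SS=SS, II=II)
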