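import numpy as np
import pytest

from ktom.agents import make_agent
from ktom.game import play_game


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """One simulated 60-trial session (influence seeker vs 0-ToM hider)."""
    return play_game(
        make_agent("Inf", role="seeker"),
        make_agent("0-ToM", role="hider"),
        60,
        seed=42,
    )


@pytest.fixture(scope="session")
def random_sessions():
    """Ten sessions between a biased-Nash seeker and assorted hiders."""
    out = []
    for i, opp in enumerate(["RB", "0-ToM", "1-ToM", "2-ToM", "RB",
                             "0-ToM", "1-ToM", "2-ToM", "RB", "0-ToM"]):
        out.append(
            play_game(
                make_agent("BN", role="seeker", bias=0.3 if i % 2 else 0.0),
                make_agent(opp, role="hider", seed=100 + i),
                60,
                seed=100 + i,
                opponent=opp,
            )
        )
    return out
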