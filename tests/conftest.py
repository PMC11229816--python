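import numpy as np
import pytest

from recbreak.simulate import (
    SimulationConfig,
    simulate_arg,
    simulate_sequences,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def triplet_type3():
    """A well-conditioned Type III single-breakpoint triplet simulation:
    central breakpoint and non-degenerate realized diversity."""
    rng = np.random.default_rng(71)
    cfg = SimulationConfig(
        sample_size=3, recomb_rate=1e-3, diversity=0.15,
        min_events=1, max_events=1, child_is_sample=True,
    )
    while True:
        arg = simulate_arg(cfg, rng)
        if arg.events[0].event_type != "III":
            continue
        if not 300 <= arg.events[0].breakpoint <= 700:
            continue
        aln = simulate_sequences(arg, rng=rng)
        if aln.pairwise_diversity() >= 0.08:
            return arg, aln


@pytest.fixture(scope="session")
def multi_arg_aln():
    """A 10-sample multiple-breakpoint simulation with >= 2 events."""
    rng = np.random.default_rng(72)
    cfg = SimulationConfig(
        sample_size=10, recomb_rate=2e-3, diversity=0.2,
        min_events=2, max_events=10, exclude_type1=True,
    )
    arg = simulate_arg(cfg, rng)
    aln = simulate_sequences(arg, rng=rng)
    return arg, aln
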