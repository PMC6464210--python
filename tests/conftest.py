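import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite",
        derandomize=True,
        max_examples=40,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cultivar set shared across tests."""
    from plastotype.simulate import SyntheticSpec, simulate_plastome_set

    return simulate_plastome_set(SyntheticSpec(seed=11))
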