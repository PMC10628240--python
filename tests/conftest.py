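import numpy as np
import pytest

from fvgraft import germline, synthetic
from fvgraft.examples import load_example_case


@pytest.fixture(scope="session")
def example_case():
    return load_example_case()


@pytest.fixture(scope="session")
def heavy_library():
    return germline.default_library("heavy")


@pytest.fixture(scope="session")
def light_library():
    return germline.default_library("light")


def fuzzed_fv_spec(seed: int) -> tuple[str, synthetic.FvSpec]:
    """Deterministic random Fv spec over the generator's supported space."""
    chain_type = "heavy" if seed % 2 == 0 else "light"
    rng = np.random.default_rng(seed + 10_000)
    if chain_type == "heavy":
        cdrs = (int(rng.integers(5, 8)), int(rng.integers(16, 20)), int(rng.integers(8, 20)))
        ins = ((82, int(rng.integers(1, 4))),) if rng.random() < 0.5 else ()
    else:
        cdrs = (int(rng.integers(11, 18)), 7, int(rng.integers(9, 16)))
        ins = ((106, 1),) if rng.random() < 0.3 else ()
    return chain_type, synthetic.FvSpec(chain_type, cdrs, ins, "randomized")
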