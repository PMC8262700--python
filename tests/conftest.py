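import numpy as np
import pytest

from smallrna.simulate import SimulationSpec, make_toy_bundle


@pytest.fixture(scope="session")
def toy_bundle():
    spec = SimulationSpec(seed=11, n_mirnas=5, n_other={"rRNA": 3}, genome_len=20_000)
    bundle, truth = make_toy_bundle(spec)
    return bundle, truth, spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
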