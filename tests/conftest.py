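import numpy as np
import pytest

from cycletx import Genome, TranscriptionParams, make_uniform_genome


@pytest.fixture
def three_gene_genome() -> Genome:
    return Genome.from_lengths([1.0, 2.0, 3.0])


@pytest.fixture
def serial_params() -> TranscriptionParams:
    return TranscriptionParams(rate=1.0, serial_mode=True)


@pytest.fixture
def concurrent_params() -> TranscriptionParams:
    return TranscriptionParams(rate=1.0, reinit_spacing=0.25, serial_mode=False)


@pytest.fixture
def ten_gene_genome() -> Genome:
    return make_uniform_genome(10, 1, 10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
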