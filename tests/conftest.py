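"""Shared fixtures: small deterministic datasets built by the simulator."""

import numpy as np
import pytest

from denovotx.config import RunConfig
from denovotx.io import Read
from denovotx.simulate import SimSpec, generate_dataset


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def rna_cfg():
    return RunConfig(rna_mode=True)


@pytest.fixture
def small_dataset():
    """10 single-isoform genes x 10 stranded reads at 7% error."""
    spec = SimSpec(n_genes=10, reads_per_transcript=10, seed=1)
    return generate_dataset(spec)


@pytest.fixture
def reads_by_id(small_dataset):
    return {r.read_id: r for r in small_dataset.reads}


def make_read(read_id: str, seq: str, q: int = 20) -> Read:
    return Read(read_id, seq, np.full(len(seq), q, dtype=int))


@pytest.fixture
def read_factory():
    return make_read
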