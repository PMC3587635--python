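import numpy as np
import pytest

from ssrmir.io_formats import Transcript, write_fasta
from ssrmir.synthetic_data import SynthConfig, TargetSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def fasta_factory(tmp_path):
    """Write a dict of id -> sequence as a FASTA file and return its path."""

    def _make(records, name="test.fasta"):
        path = tmp_path / name
        write_fasta(
            [Transcript(id=k, seq=v) for k, v in records.items()], path
        )
        return path

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted transcriptome shared across tests (one generation)."""
    return generate(
        SynthConfig(
            n_transcripts=10,
            n_compliant=3,
            n_decoys=4,
            target_spec=TargetSpec(n_sites=5),
            seed=11,
        )
    )
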