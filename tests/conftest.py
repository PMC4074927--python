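import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from entroclust import GenomeSequence, clean_sequence

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20140530)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write a FASTA file from (header, seq) pairs; returns the path."""

    def _write(name, records):
        p = tmp_path / name
        with open(p, "wt") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return p

    return _write


@pytest.fixture
def random_genome(rng):
    """A 20 kb uniform-composition genome for structural tests."""
    bases = rng.choice(list("ACGT"), size=20_000)
    return GenomeSequence(
        label="rand20k", residues="".join(bases), source_length=20_000, removed_count=0
    )


def make_genome(label, residues):
    return clean_sequence(residues, label=label)
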