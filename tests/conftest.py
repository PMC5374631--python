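import numpy as np
import pytest

from rbpbind import (
    GenomeSource,
    LabeledSequenceSet,
    MotifModel,
    SequenceRecord,
    synth_generate,
)


@pytest.fixture(scope="session")
def planted_motif() -> MotifModel:
    """The default informative motif: ACGUACGUA core at 0.85 planted in a
    25-nt uniform background."""
    return MotifModel.planted()


@pytest.fixture(scope="session")
def synth_data(planted_motif) -> LabeledSequenceSet:
    """A small motif-planted dataset for pipeline-level tests."""
    return synth_generate(planted_motif, n_pos=300, n_neg=300, n_groups=4, seed=11)


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeSource:
    """A two-chromosome toy genome with one 'N' patch on chr2."""
    rng = np.random.default_rng(42)
    chr1 = "".join(rng.choice(list("ACGT"), size=600))
    chr2 = "".join(rng.choice(list("ACGT"), size=300))
    chr2 = chr2[:100] + "NNNNN" + chr2[105:]
    return GenomeSource({"chr1": chr1, "chr2": chr2})


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_records(seqs, label="unknown", rbp=None):
    return [
        SequenceRecord(id=f"s{i}", sequence=s, label=label, rbp=rbp)
        for i, s in enumerate(seqs)
    ]
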