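import numpy as np
import pytest

from introscan.alignment import Alignment, SequenceRecord


def make_alignment(seqs, species=None, mask=None):
    """Build a small labelled alignment from id->residues pairs."""
    species = species or {}
    records = [
        SequenceRecord(
            id=name,
            species=species.get(name, "spA"),
            collection="c1",
            residues=res,
        )
        for name, res in seqs.items()
    ]
    return Alignment(records=records, site_mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_924)


@pytest.fixture
def toy_alignment():
    return make_alignment(
        {"a": "ACGTACGT", "b": "ACGTACGA", "c": "ACGTACGT", "d": "ACTTACGA"}
    )
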