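from __future__ import annotations

import random

import pytest

from barcode_assign.seqio import BarcodeRecord


@pytest.fixture
def make_record():
    """Factory for quick test records."""

    def factory(record_id="Q1", taxon="Genus_species", marker="rbcLa",
                sequence="ACGT" * 25, flags=()):
        return BarcodeRecord(
            record_id=record_id, taxon_raw=taxon, marker=marker,
            sequence=sequence, flags=frozenset(flags),
        )

    return factory


@pytest.fixture
def rng():
    return random.Random(20240517)


@pytest.fixture
def random_seq(rng):
    def factory(n, alphabet="ACGT"):
        return "".join(rng.choice(alphabet) for _ in range(n))

    return factory


@pytest.fixture
def write_records(tmp_path):
    """Write records to a temp FASTA and return the path."""
    from barcode_assign.seqio import BOLD_DIALECT, write_fasta

    def factory(records, name="test.fasta", dialect=BOLD_DIALECT):
        path = tmp_path / name
        write_fasta(records, path, dialect)
        return path

    return factory
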