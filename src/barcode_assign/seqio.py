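"""Barcode FASTA I/O in a BOLD-like header dialect.

Reference databases for plant DNA barcoding (rbcLa, matK, trnH-psbA) are
distributed as FASTA files whose headers pack a record identifier, a
taxonomy string and a marker name into a single line.  This module reads
and writes that dialect, canonicalizes headers (spaces replaced, fields in
a fixed order), applies the reference-inclusion filter (family whitelist,
no contaminant flags, length strictly greater than a cutoff) and produces
per-marker length/ambiguity summaries.

The packaged study fixtures (specimen table and per-species assignment
fractions) are loaded from here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, FastaParseError, SequenceValidationError

#: IUPAC nucleotide one-letter codes (upper-case); gaps are not allowed in records.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

#: Default marker vocabulary of the three plastid barcodes used in the study design.
DEFAULT_MARKERS = ("rbcLa", "matK", "trnH-psbA")

#: Header tokens that mark a record as a contaminant (case-insensitive).
DEFAULT_CONTAMINANT_FLAGS = frozenset({"contaminant", "contamination"})


@dataclass(frozen=True)
class FastaDialect:
    """How header fields are packed into a FASTA description line.

    ``field_order`` names the semantic fields in order; it must contain
    ``record_id`` and ``taxon`` exactly once.  ``marker`` and ``extra``
    are optional.  ``space_replacement`` is the character substituted for
    spaces inside the taxon when canonicalizing.
    """

    field_separator: str = "|"
    field_order: tuple[str, ...] = ("record_id", "taxon", "marker")
    space_replacement: str = "_"

    def __post_init__(self) -> None:
        for required in ("record_id", "taxon"):
            if self.field_order.count(required) != 1:
                raise ConfigError(
                    f"dialect field_order must contain {required!r} exactly once: "
                    f"{self.field_order}"
                )


#: The canonical dialect: ``>record_id|taxon_with_underscores|marker``.
BOLD_DIALECT = FastaDialect()


@dataclass
class BarcodeRecord:
    """One barcode sequence flowing through the pipeline.

    ``record_id`` is an opaque identifier (e.g. a BOLD process ID such as
    ``SWFRG013-19``); ``taxon_raw`` is the free-text taxonomy string from
    the header; ``marker`` names the barcode locus; ``flags`` holds any
    extra header tokens (contaminant marks and the like).
    """

    record_id: str
    taxon_raw: str
    sequence: str
    marker: str | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = self.validate_sequence(self.sequence)
        if bad is not None:
            pos, ch = bad
            raise SequenceValidationError(
                f"record {self.record_id!r}: non-IUPAC character {ch!r} "
                f"at position {pos + 1}"
            )

    @staticmethod
    def validate_sequence(sequence: str) -> tuple[int, str] | None:
        """Return (position, char) of the first invalid character, or None."""
        if not sequence:
            return (0, "")
        for i, ch in enumerate(sequence):
            if ch.upper() not in IUPAC_NUCLEOTIDES:
                return (i, ch)
        return None

    def length(self) -> int:
        return len(self.sequence)

    def n_count(self) -> int:
        return sum(1 for ch in self.sequence if ch in "Nn")

    def header(self, dialect: FastaDialect = BOLD_DIALECT) -> str:
        """Serialize the record's description line under ``dialect``."""
        parts = []
        for name in dialect.field_order:
            if name == "record_id":
                parts.append(self.record_id)
            elif name == "taxon":
                parts.append(
                    self.taxon_raw.replace(" ", dialect.space_replacement)
                )
            elif name == "marker":
                if self.marker is None:
                    raise FastaParseError(
                        f"record {self.record_id!r}: dialect requires a marker "
                        "field but the record has none"
                    )
                parts.append(self.marker)
            elif name == "extra":
                parts.append(";".join(sorted(self.flags)))
            else:  # pragma: no cover - dialect constructor guards field names
                raise ConfigError(f"unknown dialect field {name!r}")
        return dialect.field_separator.join(parts)


def _parse_header(description: str, dialect: FastaDialect) -> dict[str, str]:
    parts = description.split(dialect.field_separator)
    if len(parts) < len(dialect.field_order):
        raise FastaParseError(
            f"header {description!r}: expected at least "
            f"{len(dialect.field_order)} {dialect.field_separator!r}-separated "
            f"fields ({', '.join(dialect.field_order)}), got {len(parts)}"
        )
    fields = dict(zip(dialect.field_order, parts))
    extra_tail = parts[len(dialect.field_order):]
    if extra_tail:
        fields["extra"] = ";".join([fields.get("extra", ""), *extra_tail]).strip(";")
    return fields


def read_fasta(path, dialect: FastaDialect = BOLD_DIALECT) -> list[BarcodeRecord]:
    """Read a FASTA file into :class:`BarcodeRecord` objects, in file order.

    Raises :class:`FastaParseError` on sequence data before the first
    header (naming the line) or on headers with too few fields, and
    :class:`SequenceValidationError` on non-IUPAC characters.  Duplicate
    record IDs within the file are an error.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            break

    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(entry.description, dialect)
        seq = str(entry.seq).replace(" ", "").replace("\t", "")
        flag_text = fields.get("extra", "")
        flags = frozenset(t for t in flag_text.split(";") if t)
        record = BarcodeRecord(
            record_id=fields["record_id"],
            taxon_raw=fields["taxon"],
            marker=fields.get("marker"),
            sequence=seq,
            flags=flags,
        )
        if record.record_id in seen:
            raise FastaParseError(
                f"{path}: duplicate record_id {record.record_id!r}"
            )
        seen.add(record.record_id)
        records.append(record)
    return records


def write_fasta(
    records: Iterable[BarcodeRecord],
    path,
    dialect: FastaDialect = BOLD_DIALECT,
    line_width: int = 70,
) -> None:
    """Write records as FASTA with headers serialized under ``dialect``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.header(dialect)}\n")
            seq = rec.sequence
            if line_width:
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")
            else:
                fh.write(seq + "\n")


def reformat_headers(
    records: Sequence[BarcodeRecord],
    dialect_out: FastaDialect = BOLD_DIALECT,
) -> list[BarcodeRecord]:
    """Canonicalize taxon strings for serialization under ``dialect_out``.

    Internal spaces in the taxonomy are replaced by the dialect's
    ``space_replacement`` so downstream tools that split on whitespace
    keep the full label.  Idempotent: already-canonical records pass
    through unchanged.
    """
    out = []
    for rec in records:
        if "marker" in dialect_out.field_order and rec.marker is None:
            raise FastaParseError(
                f"record {rec.record_id!r}: output dialect requires a marker "
                "field but the record has none"
            )
        taxon = rec.taxon_raw.replace(" ", dialect_out.space_replacement)
        out.append(replace(rec, taxon_raw=taxon))
    return out


def filter_reference(
    records: Sequence[BarcodeRecord],
    allowed_families: Iterable[str],
    min_length_exclusive: int = 200,
    *,
    family_of: Callable[[BarcodeRecord], str | None] | None = None,
    contaminant_flags: frozenset[str] = DEFAULT_CONTAMINANT_FLAGS,
    on_unresolved: str = "drop",
) -> list[BarcodeRecord]:
    """Apply the reference-inclusion rule.

    A record is retained iff its family is in ``allowed_families``, none of
    its header flags is a contaminant token, and its length is *strictly*
    greater than ``min_length_exclusive`` (default 200 bp, i.e. >= 201 bp
    survives).  ``family_of`` resolves a record to its family; by default
    the packaged study species->family lookup is consulted on the binomial.
    Records whose family cannot be resolved are dropped (``on_unresolved=
    "drop"``) or raise (``"error"``).
    """
    if on_unresolved not in ("drop", "error"):
        raise ConfigError(f"on_unresolved must be 'drop' or 'error', got {on_unresolved!r}")
    if family_of is None:
        lookup = load_family_lookup()
        family_of = family_from_lookup(lookup)
    allowed = {f.lower() for f in allowed_families}
    contaminants = {f.lower() for f in contaminant_flags}

    kept: list[BarcodeRecord] = []
    for rec in records:
        fam = family_of(rec)
        if fam is None:
            if on_unresolved == "error":
                raise ConfigError(
                    f"record {rec.record_id!r}: family of taxon "
                    f"{rec.taxon_raw!r} could not be resolved"
                )
            continue
        if fam.lower() not in allowed:
            continue
        if any(f.lower() in contaminants for f in rec.flags):
            continue
        if rec.length() <= min_length_exclusive:
            continue
        kept.append(rec)
    return kept


def family_from_lookup(
    lookup: Mapping[str, str],
) -> Callable[[BarcodeRecord], str | None]:
    """Build a ``family_of`` resolver from a binomial->family mapping."""
    normalized = {k.replace("_", " ").strip().lower(): v for k, v in lookup.items()}

    def family_of(rec: BarcodeRecord) -> str | None:
        from .taxonomy import parse_taxon

        label = parse_taxon(rec.taxon_raw)
        binomial = label.binomial()
        if binomial is not None and binomial.lower() in normalized:
            return normalized[binomial.lower()]
        return normalized.get(label.genus.lower())

    return family_of


@dataclass(frozen=True)
class MarkerSummary:
    """Per-marker sequence accounting (count, length extrema, total N's)."""

    marker: str
    count: int
    min_length: int | None
    max_length: int | None
    total_n: int


def summarize(records: Sequence[BarcodeRecord], marker: str) -> MarkerSummary:
    """Summarize the records of one marker; extrema are None when count is 0."""
    lengths = [r.length() for r in records if r.marker == marker]
    total_n = sum(r.n_count() for r in records if r.marker == marker)
    if not lengths:
        return MarkerSummary(marker, 0, None, None, 0)
    return MarkerSummary(marker, len(lengths), min(lengths), max(lengths), total_n)


# ---------------------------------------------------------------------------
# Packaged study fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("barcode_assign.data").joinpath(name)


def load_specimen_table() -> pd.DataFrame:
    """The study's specimen x marker accounting table.

    Columns: record_id, species, cultivar, marker, length, n_count, failed.
    ``failed`` marks specimen x marker combinations with repeatedly
    unsuccessful PCR (no sequence obtained; length and n_count are 0).
    """
    with resources.as_file(_data_path("table1.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_fraction_table() -> pd.DataFrame:
    """Per-(family, species, marker) correct/total assignment fractions.

    Columns: family, species, marker, n_correct, n_total — the published
    species-level outcome of the study's own BLAST-based assignment run
    against the 2019 reference download.
    """
    with resources.as_file(_data_path("table3.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_family_lookup() -> dict[str, str]:
    """Species binomial -> family for the 16 study species."""
    with resources.as_file(_data_path("families.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["species"], df["family"]))


def specimen_records(
    table: pd.DataFrame | None = None,
    seed: int = 0,
) -> list[BarcodeRecord]:
    """Materialize the specimen table as records with synthetic base calls.

    The published table reports lengths and ambiguity counts but not the
    base calls themselves, so sequences are drawn at random (seeded) at
    the recorded length with the recorded number of N's, giving a fully
    in-memory dataset with the study's exact accounting structure.
    Failed specimen x marker combinations yield no record.
    """
    import numpy as np

    if table is None:
        table = load_specimen_table()
    rng = np.random.default_rng(seed)
    records = []
    for row in table.itertuples(index=False):
        if row.failed:
            continue
        seq = rng.choice(list("ACGT"), size=row.length)
        if row.n_count:
            pos = rng.choice(row.length, size=row.n_count, replace=False)
            seq[pos] = "N"
        records.append(
            BarcodeRecord(
                record_id=f"{row.record_id}.{row.marker}",
                taxon_raw=str(row.species).replace(" ", "_"),
                marker=row.marker,
                sequence="".join(seq),
            )
        )
    return records
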