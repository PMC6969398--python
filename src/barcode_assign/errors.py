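"""Exception hierarchy for the barcode-assignment pipeline.

Every stage raises a subclass of :class:`BarcodeAssignError`, so callers
(and the CLI) can distinguish user-input problems from internal faults.
"""


class BarcodeAssignError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(BarcodeAssignError):
    """Invalid configuration or parameter combination."""


class FastaParseError(BarcodeAssignError):
    """Malformed FASTA input; message names the offending line or record."""


class SequenceValidationError(BarcodeAssignError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class TaxonomyError(BarcodeAssignError):
    """A taxonomy string could not be parsed or resolved."""


class HitTableError(BarcodeAssignError):
    """Malformed tabular hit input (12-column BLAST-style layout)."""


class SearchError(BarcodeAssignError):
    """Invalid similarity-search request (empty database, marker mismatch...)."""


class AssignmentError(BarcodeAssignError):
    """Inconsistent assignment inputs (unknown IDs, unknown policy)."""


class RatesError(BarcodeAssignError):
    """Invalid rate aggregation request (empty group, unknown species)."""
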