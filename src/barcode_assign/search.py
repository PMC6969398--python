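"""Similarity search producing BLAST-tabular (outfmt 6) compatible hits.

The assignment workflow only needs a *ranking* of database sequences per
query, but it speaks the 12-column tabular hit format so that externally
produced hit tables (e.g. from a real ``blastn -outfmt 6`` run) can be
dropped in unchanged.  The in-repo engine computes maximal-scoring local
alignments under affine gap costs (Smith-Waterman semantics, literal
IUPAC letter matching) and converts raw scores to bit scores and
E-values with Karlin-Altschul statistics:

    bitscore = (lambda * raw - ln K) / ln 2
    evalue   = m * n * 2 ** (-bitscore)

where m is the query length and n the total database length (no
finite-size edge correction; assignment depends only on score ranking).

Scoring presets mirror common nucleotide-search parameterizations; the
gapped lambda/K constants per preset are the published values for those
score sets.  For ungapped scoring, :func:`estimate_lambda` solves the
characteristic equation sum_ij p_i p_j exp(lambda s_ij) = 1 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement
from scipy.optimize import brentq

from .errors import ConfigError, HitTableError, SearchError
from .seqio import BarcodeRecord

_ALPHABET = "ACGTRYSWKMBDHVN"


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul lambda and K.

    ``gap_open`` is the cost of opening a gap and ``gap_extend`` the cost
    per gap position, so a gap of length k costs gap_open + k*gap_extend
    (the BLAST convention).  ``lam`` is in nats per raw-score unit.
    """

    match_reward: int
    mismatch_penalty: int
    gap_open: int
    gap_extend: int
    lam: float
    K: float
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ConfigError("match_reward must be positive")
        if self.mismatch_penalty >= 0:
            raise ConfigError("mismatch_penalty must be negative")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ConfigError("gap_open must be >= 0 and gap_extend > 0")
        if self.lam <= 0 or self.K <= 0:
            raise ConfigError("lambda and K must be positive")


#: Named presets with published gapped-regime lambda/K for their score sets.
PRESETS: dict[str, ScoringScheme] = {
    # blastn task defaults: reward +2 / penalty -3, gap 5/2
    "blastn-task": ScoringScheme(2, -3, 5, 2, lam=0.625, K=0.41,
                                 preset_name="blastn-task"),
    # megablast-like: reward +1 / penalty -2, linear gap cost 2 per position
    "megablast-like": ScoringScheme(1, -2, 0, 2, lam=1.28, K=0.46,
                                    preset_name="megablast-like"),
}

DEFAULT_PRESET = "blastn-task"


def get_preset(name: str) -> ScoringScheme:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown scoring preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def estimate_lambda(
    scheme: ScoringScheme,
    base_frequencies: Sequence[float] | None = None,
    rel_tol: float = 1e-12,
) -> float:
    """Ungapped Karlin-Altschul lambda for a match/mismatch score set.

    Solves sum_i sum_j p_i p_j exp(lambda * s_ij) = 1 for the unique
    positive root, where s_ij is ``match_reward`` on the diagonal and
    ``mismatch_penalty`` off it.  Requires a negative expected score per
    aligned pair (otherwise the statistics are undefined).
    """
    p = np.full(4, 0.25) if base_frequencies is None else np.asarray(
        base_frequencies, dtype=float
    )
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ConfigError("base_frequencies must be a 4-vector summing to 1")
    p_match = float(np.sum(p * p))
    p_mismatch = 1.0 - p_match
    expected = p_match * scheme.match_reward + p_mismatch * scheme.mismatch_penalty
    if expected >= 0:
        raise ConfigError(
            f"expected score per aligned pair is {expected:.4f} >= 0; "
            "Karlin-Altschul statistics are undefined"
        )

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * scheme.match_reward)
            + p_mismatch * math.exp(lam * scheme.mismatch_penalty)
            - 1.0
        )

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - unreachable for valid scores
            raise ConfigError("failed to bracket lambda")
    return float(brentq(f, 1e-12, hi, rtol=rel_tol))


def bit_and_evalue(
    raw_score: float,
    scheme: ScoringScheme,
    query_length: int,
    db_length: int,
) -> tuple[float, float]:
    """Convert a raw alignment score to (bitscore, evalue).

    Uses the raw search-space product m*n without effective-length
    correction; see module docstring.
    """
    bits = (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)
    try:
        evalue = query_length * db_length * math.pow(2.0, -bits)
    except OverflowError:
        evalue = math.inf
    return bits, evalue


# ---------------------------------------------------------------------------
# Local alignment engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    """The maximal-scoring local alignment of one query/subject pair.

    Coordinates are 1-based inclusive on the input sequences as given
    (strand handling happens in :func:`search_all`).
    """

    raw_score: float
    length: int
    identities: int
    mismatches: int
    gap_openings: int
    gap_columns: int
    qstart: int
    qend: int
    sstart: int
    send: int

    @property
    def pident(self) -> float:
        return 100.0 * self.identities / self.length if self.length else 0.0


@lru_cache(maxsize=8)
def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = match if a == b else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(query: str, subject: str, scheme: ScoringScheme) -> LocalAlignment:
    """Best local alignment of ``query`` vs ``subject`` under ``scheme``.

    Ambiguity letters score as mismatches unless they literally match
    (N aligned to N scores as a match).  Among co-optimal alignments the
    engine reports its deterministic first traversal; the raw score is
    unique.  Raises on empty input.
    """
    if not query or not subject:
        raise SearchError("cannot align empty sequences")
    q, s = query.upper(), subject.upper()
    bad_q = BarcodeRecord.validate_sequence(q)
    bad_s = BarcodeRecord.validate_sequence(s)
    if bad_q is not None or bad_s is not None:
        pos, ch = bad_q if bad_q is not None else bad_s
        raise SearchError(f"non-IUPAC character {ch!r} at position {pos + 1}")
    aligner = _aligner(
        scheme.match_reward, scheme.mismatch_penalty,
        scheme.gap_open, scheme.gap_extend,
    )
    score = float(aligner.score(q, s))
    if score <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
    aln = aligner.align(q, s)[0]
    coords = aln.coordinates
    identities = mismatches = gap_openings = gap_columns = 0
    length = 0
    for i in range(coords.shape[1] - 1):
        dq = int(coords[0, i + 1] - coords[0, i])
        ds = int(coords[1, i + 1] - coords[1, i])
        if dq and ds:  # aligned block
            block_q = q[coords[0, i]:coords[0, i + 1]]
            block_s = s[coords[1, i]:coords[1, i + 1]]
            same = sum(1 for x, y in zip(block_q, block_s) if x == y)
            identities += same
            mismatches += dq - same
            length += dq
        else:  # gap segment in one of the two sequences
            gap_openings += 1
            gap_columns += max(dq, ds)
            length += max(dq, ds)
    return LocalAlignment(
        raw_score=score,
        length=length,
        identities=identities,
        mismatches=mismatches,
        gap_openings=gap_openings,
        gap_columns=gap_columns,
        qstart=int(coords[0, 0]) + 1,
        qend=int(coords[0, -1]),
        sstart=int(coords[1, 0]) + 1,
        send=int(coords[1, -1]),
    )


# ---------------------------------------------------------------------------
# Hits and tabular I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    """One row of a 12-column BLAST-tabular hit table."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def to_line(self) -> str:
        return "\t".join([
            self.qseqid,
            self.sseqid,
            f"{self.pident:.2f}",
            str(self.length),
            str(self.mismatch),
            str(self.gapopen),
            str(self.qstart),
            str(self.qend),
            str(self.sstart),
            str(self.send),
            _format_evalue(self.evalue),
            f"{self.bitscore:.1f}",
        ])


def _format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    if 1e-3 <= e < 1e4:
        return f"{e:.3g}"
    return f"{e:.2e}"


_NUMERIC_FIELDS = (
    ("pident", float), ("length", int), ("mismatch", int), ("gapopen", int),
    ("qstart", int), ("qend", int), ("sstart", int), ("send", int),
    ("evalue", float), ("bitscore", float),
)


def read_outfmt6(path) -> list[Hit]:
    """Parse a 12-column tab-separated hit table; errors name the line."""
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise HitTableError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(parts)}"
                )
            values: dict[str, object] = {"qseqid": parts[0], "sseqid": parts[1]}
            for (name, conv), text in zip(_NUMERIC_FIELDS, parts[2:]):
                try:
                    values[name] = conv(text)
                except ValueError:
                    raise HitTableError(
                        f"{path}: line {lineno}: field {name!r} is not "
                        f"{conv.__name__}: {text!r}"
                    ) from None
            hits.append(Hit(**values))  # type: ignore[arg-type]
    return hits


def write_outfmt6(hits: Iterable[Hit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.to_line() + "\n")


# ---------------------------------------------------------------------------
# All-vs-all search
# ---------------------------------------------------------------------------

def _words(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def search_all(
    queries: Sequence[BarcodeRecord],
    references: Sequence[BarcodeRecord],
    scheme: ScoringScheme | None = None,
    max_targets: int = 50,
    evalue_cutoff: float = 10.0,
    *,
    exhaustive: bool = False,
    word_size: int = 11,
    both_strands: bool = True,
) -> list[Hit]:
    """Align every query against a one-marker reference database.

    All queries and references must carry the same marker (one database
    per barcode).  By default candidate pairs are prefiltered to those
    sharing at least one exact ``word_size``-mer on either strand, then
    fully aligned; ``exhaustive=True`` aligns every pair.  Both strands
    are searched and the better-scoring one reported, with minus-strand
    alignments written subject-descending (sstart > send).  Hits are
    sorted per query by descending bitscore then ascending sseqid and
    truncated to ``max_targets``.
    """
    if scheme is None:
        scheme = PRESETS[DEFAULT_PRESET]
    if not references:
        raise SearchError("empty reference database")
    if not queries:
        return []
    markers = {r.marker for r in list(queries) + list(references)}
    if len(markers) > 1:
        raise SearchError(
            f"queries and references must share one marker, got {sorted(map(str, markers))}"
        )

    db_length = sum(r.length() for r in references)
    index: dict[str, set[int]] | None = None
    if not exhaustive:
        index = {}
        for i, ref in enumerate(references):
            for w in _words(ref.sequence, word_size):
                index.setdefault(w, set()).add(i)

    all_hits: list[Hit] = []
    for query in queries:
        qseq = query.sequence.upper()
        qlen = len(qseq)
        rc = reverse_complement(qseq) if both_strands else None
        if index is None:
            candidates: Iterable[int] = range(len(references))
        else:
            cand: set[int] = set()
            for w in _words(qseq, word_size):
                cand |= index.get(w, set())
            if rc is not None:
                for w in _words(rc, word_size):
                    cand |= index.get(w, set())
            candidates = sorted(cand)

        query_hits: list[Hit] = []
        for i in candidates:
            ref = references[i]
            fwd = local_align(qseq, ref.sequence, scheme)
            best, minus = fwd, False
            if rc is not None:
                rev = local_align(rc, ref.sequence, scheme)
                if rev.raw_score > fwd.raw_score:
                    best, minus = rev, True
            if best.raw_score <= 0:
                continue
            bits, evalue = bit_and_evalue(best.raw_score, scheme, qlen, db_length)
            if evalue > evalue_cutoff:
                continue
            if minus:
                qstart = qlen - best.qend + 1
                qend = qlen - best.qstart + 1
                sstart, send = best.send, best.sstart
            else:
                qstart, qend = best.qstart, best.qend
                sstart, send = best.sstart, best.send
            query_hits.append(Hit(
                qseqid=query.record_id,
                sseqid=ref.record_id,
                pident=round(best.pident, 2),
                length=best.length,
                mismatch=best.mismatches,
                gapopen=best.gap_openings,
                qstart=qstart,
                qend=qend,
                sstart=sstart,
                send=send,
                evalue=evalue,
                bitscore=round(bits, 1),
            ))
        query_hits.sort(key=lambda h: (-h.bitscore, h.sseqid))
        all_hits.extend(query_hits[:max_targets])
    return all_hits
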