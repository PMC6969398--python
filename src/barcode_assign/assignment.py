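"""The matcher stage: self-hit removal, top-hit selection, match calling.

Each query specimen is effectively identified by the rest of the
database: its own record is removed from the hit list (a *self-hit* is a
hit whose subject ID equals the query ID — nothing more), the remaining
hits with the maximal bit score are selected, and a species-level
(genus-level) match is called when the query's binomial (genus) equals
that of the top hit or hits.  When tied top hits disagree among
themselves, a *tie policy* decides the call:

``any``
    a match if at least one top hit agrees (default),
``all``
    a match only if every top hit agrees,
``majority``
    a match if more than half agree.

Ties are detected on the printed-precision bit score (1 decimal), which
is what a parser of tabular BLAST output can see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import AssignmentError
from .search import Hit
from .seqio import BarcodeRecord
from .taxonomy import CorrectionMap, TaxonLabel, correct, parse_taxon, same_genus, same_species

POLICIES = ("any", "all", "majority")


@dataclass(frozen=True)
class AssignmentResult:
    """Per-query verdicts plus the top hits that justify them."""

    qseqid: str
    query_taxon: TaxonLabel
    top_hits: tuple[tuple[str, TaxonLabel, float], ...]  # (sseqid, taxon, bitscore)
    species_match: bool
    genus_match: bool
    no_hit: bool
    tie_policy: str
    marker: str | None = None


def remove_self_hits(hits: Iterable[Hit]) -> list[Hit]:
    """Drop hits whose subject is the query itself; order preserved."""
    return [h for h in hits if h.sseqid != h.qseqid]


def top_hits(hits_for_one_query: Sequence[Hit], tie_tolerance: float = 0.0) -> list[Hit]:
    """Hits within ``tie_tolerance`` of the maximal printed bit score.

    Expects the hits of a single query with self-hits already removed.
    Empty input yields an empty list (the caller marks ``no_hit``).
    """
    if tie_tolerance < 0:
        raise AssignmentError("tie_tolerance must be non-negative")
    if not hits_for_one_query:
        return []
    qids = {h.qseqid for h in hits_for_one_query}
    if len(qids) > 1:
        raise AssignmentError(f"hits of several queries passed to top_hits: {sorted(qids)}")
    best = max(round(h.bitscore, 1) for h in hits_for_one_query)
    return [h for h in hits_for_one_query if round(h.bitscore, 1) >= best - tie_tolerance]


def call_match(
    query_taxon: TaxonLabel,
    top_taxa: Sequence[TaxonLabel],
    level: str,
    policy: str = "any",
) -> bool:
    """Call a match at ``level`` ("species" or "genus") under ``policy``."""
    if policy not in POLICIES:
        raise AssignmentError(f"unknown tie policy {policy!r}; expected one of {POLICIES}")
    if level not in ("species", "genus"):
        raise AssignmentError(f"unknown level {level!r}")
    if not top_taxa:
        return False
    cmp = same_species if level == "species" else same_genus
    agree = sum(1 for t in top_taxa if cmp(query_taxon, t))
    if policy == "any":
        return agree >= 1
    if policy == "all":
        return agree == len(top_taxa)
    return agree * 2 > len(top_taxa)


def assign_all(
    queries: Sequence[BarcodeRecord],
    hits: Sequence[Hit],
    references: Sequence[BarcodeRecord] | Mapping[str, str] | None = None,
    corrections: CorrectionMap | None = None,
    policy: str = "any",
    tie_tolerance: float = 0.0,
    exclude_ids: Iterable[str] = (),
) -> list[AssignmentResult]:
    """Produce one :class:`AssignmentResult` per query.

    Subject taxonomies are resolved from ``references`` (a record list or
    an id -> taxonomy-string mapping); when omitted, the queries
    themselves double as the reference lookup (the leave-out design
    where the database contains the query specimens).  Hits naming an
    unknown query or subject raise.  ``exclude_ids`` removes additional
    subject records before matching (stricter leave-out experiments);
    queries with no surviving hit are flagged ``no_hit`` and count as
    incorrect downstream.
    """
    if corrections is None:
        corrections = CorrectionMap.default()

    taxon_of: dict[str, str] = {}
    if references is None:
        references = queries
    if isinstance(references, Mapping):
        taxon_of.update(references)
    else:
        for rec in references:
            taxon_of[rec.record_id] = rec.taxon_raw

    known_queries = {q.record_id for q in queries}
    for h in hits:
        if h.qseqid not in known_queries:
            raise AssignmentError(f"hit references unknown query ID {h.qseqid!r}")
        if h.sseqid not in taxon_of and h.sseqid not in known_queries:
            raise AssignmentError(f"hit references unknown subject ID {h.sseqid!r}")

    excluded = set(exclude_ids)
    by_query: dict[str, list[Hit]] = {q.record_id: [] for q in queries}
    for h in remove_self_hits(hits):
        if h.sseqid in excluded:
            continue
        by_query[h.qseqid].append(h)

    label_cache: dict[str, TaxonLabel] = {}

    def corrected_label(raw: str) -> TaxonLabel:
        if raw not in label_cache:
            label_cache[raw] = correct(parse_taxon(raw), corrections)
        return label_cache[raw]

    results: list[AssignmentResult] = []
    for q in queries:
        qlabel = corrected_label(q.taxon_raw)
        # sort for deterministic output regardless of hit-table order
        qhits = sorted(by_query[q.record_id], key=lambda h: (-round(h.bitscore, 1), h.sseqid))
        best = top_hits(qhits, tie_tolerance)
        top = tuple(
            (h.sseqid, corrected_label(taxon_of.get(h.sseqid, "")), round(h.bitscore, 1))
            for h in best
        )
        top_taxa = [t for _, t, _ in top]
        results.append(AssignmentResult(
            qseqid=q.record_id,
            query_taxon=qlabel,
            top_hits=top,
            species_match=call_match(qlabel, top_taxa, "species", policy),
            genus_match=call_match(qlabel, top_taxa, "genus", policy),
            no_hit=not best,
            tie_policy=policy,
            marker=q.marker,
        ))
    return results


def write_assignments(results: Sequence[AssignmentResult], path) -> None:
    """Write a per-query verdict TSV."""
    with open(path, "w") as fh:
        fh.write("qseqid\tmarker\tquery_binomial\ttop_hit_ids\t"
                 "top_hit_binomials\tbitscore\tspecies_match\tgenus_match\tno_hit\n")
        for r in results:
            ids = ",".join(s for s, _, _ in r.top_hits)
            taxa = ",".join(t.binomial() or t.genus for _, t, _ in r.top_hits)
            bits = f"{r.top_hits[0][2]:.1f}" if r.top_hits else ""
            fh.write("\t".join([
                r.qseqid, r.marker or "", r.query_taxon.binomial() or r.query_taxon.genus,
                ids, taxa, bits,
                str(int(r.species_match)), str(int(r.genus_match)), str(int(r.no_hit)),
            ]) + "\n")
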