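"""Correct-assignment-rate (CAR) aggregation.

Per-query match verdicts are tallied into per-(family, species, marker)
correct/total fractions, and those fractions are aggregated into grouped
percentage rates:

    CAR = 100 * (sum of correct assignments) / (total query sequences)

rounded half-up to one decimal.  Queries with no surviving hit count as
incorrect but stay in the denominator.  The module also carries the
published per-species fraction table of the study and can adjust its
denominators for the >200 bp length filter (the one sub-threshold matK
record), which is what reconciles the per-species fractions with the
published grouped percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .assignment import AssignmentResult
from .errors import RatesError
from .seqio import load_family_lookup, load_fraction_table, load_specimen_table

OVERALL = "overall"


@dataclass
class RateTable:
    """Rows keyed by (family, species, marker) with correct/total counts."""

    df: pd.DataFrame  # columns: family, species, marker, n_correct, n_total
    level: str = "species"

    def __post_init__(self) -> None:
        required = {"family", "species", "marker", "n_correct", "n_total"}
        missing = required - set(self.df.columns)
        if missing:
            raise RatesError(f"rate table missing columns {sorted(missing)}")
        bad = self.df[(self.df.n_correct < 0) | (self.df.n_correct > self.df.n_total)]
        if len(bad):
            raise RatesError(
                f"invalid counts (need 0 <= n_correct <= n_total):\n{bad}"
            )

    def markers(self) -> list[str]:
        return sorted(self.df["marker"].unique())

    def families(self) -> list[str]:
        return sorted(self.df["family"].unique())


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 48.35 -> 48.4, not banker's 48.3 or 48.2)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def per_species_fractions(
    results: Sequence[AssignmentResult],
    level: str = "species",
    family_lookup: Mapping[str, str] | None = None,
) -> RateTable:
    """Tally verdicts into one (family, species, marker) row per group.

    ``family_lookup`` maps species binomials (and/or genus names) to
    families; it defaults to the packaged study lookup.  A query species
    absent from the lookup is an error naming the species.  The result is
    independent of input order.
    """
    if level not in ("species", "genus"):
        raise RatesError(f"unknown level {level!r}")
    if family_lookup is None:
        family_lookup = load_family_lookup()
    normalized = {k.replace("_", " ").lower(): v for k, v in family_lookup.items()}

    counts: dict[tuple[str, str, str], list[int]] = {}
    for r in results:
        binomial = r.query_taxon.binomial() or r.query_taxon.genus
        family = normalized.get(binomial.lower()) or normalized.get(
            r.query_taxon.genus.lower()
        )
        if family is None:
            raise RatesError(f"species {binomial!r} missing from family lookup")
        key = (family, binomial, r.marker or "")
        c = counts.setdefault(key, [0, 0])
        c[0] += int(r.species_match if level == "species" else r.genus_match)
        c[1] += 1
    rows = [
        {"family": f, "species": s, "marker": m, "n_correct": k, "n_total": n}
        for (f, s, m), (k, n) in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["family", "species", "marker", "n_correct", "n_total"])
    return RateTable(df, level=level)


def aggregate_rate(table: RateTable, group: str, marker: str) -> float:
    """Grouped percentage CAR: 100 * sum(correct) / sum(total), half-up 1 dp.

    ``group`` is a family name or :data:`OVERALL`.  An empty group (no
    rows, or zero total) has no denominator and raises.
    """
    df = table.df[table.df.marker == marker]
    if group != OVERALL:
        df = df[df.family == group]
    total = int(df.n_total.sum())
    if total == 0:
        raise RatesError(f"no queries for group {group!r}, marker {marker!r}")
    return round_half_up(100.0 * int(df.n_correct.sum()) / total)


def load_study_fractions(
    *,
    length_filtered: bool = True,
    min_length_exclusive: int = 200,
) -> RateTable:
    """The study's published per-species species-level fraction table.

    With ``length_filtered=True`` (default) the denominators are the
    queries surviving the >200 bp inclusion filter: each obtained but
    sub-threshold sequence in the specimen table is removed from the
    corresponding (species, marker) total.  This is the denominator
    convention of the published grouped percentages.  With
    ``length_filtered=False`` the printed fractions are returned as-is
    (denominators = sequences obtained).
    """
    df = load_fraction_table().copy()
    if length_filtered:
        spec = load_specimen_table()
        short = spec[(spec.failed == 0) & (spec.length <= min_length_exclusive)]
        for row in short.itertuples(index=False):
            mask = (df.species == row.species) & (df.marker == row.marker)
            if not mask.any():
                raise RatesError(
                    f"specimen table species {row.species!r} missing from fraction table"
                )
            df.loc[mask, "n_total"] -= 1
    return RateTable(df, level="species")


def summary_frame(tables: Mapping[str, RateTable]) -> pd.DataFrame:
    """Grouped percentages for each level's table, one row per (marker, level, group)."""
    rows = []
    for level, table in tables.items():
        for marker in table.markers():
            for group in [OVERALL, *table.families()]:
                rows.append({
                    "marker": marker,
                    "level": level,
                    "group": group,
                    "percentage": aggregate_rate(table, group, marker),
                })
    return pd.DataFrame(rows, columns=["marker", "level", "group", "percentage"])


def render_rate_report(tables: Mapping[str, RateTable]) -> str:
    """TSV report: species rows as k/n strings, then grouped percentage rows.

    Consistency is asserted on every render: for each marker and level,
    the overall numerator and denominator equal the sums of the family
    numerators and denominators.
    """
    lines = ["section\tlevel\tfamily\tspecies\tmarker\tvalue"]
    for level, table in tables.items():
        for row in table.df.itertuples(index=False):
            lines.append(
                f"fractions\t{level}\t{row.family}\t{row.species}\t{row.marker}\t"
                f"{row.n_correct}/{row.n_total}"
            )
    for level, table in tables.items():
        df = table.df
        for marker in table.markers():
            sub = df[df.marker == marker]
            fam_num = sub.groupby("family").n_correct.sum()
            fam_den = sub.groupby("family").n_total.sum()
            if fam_num.sum() != sub.n_correct.sum() or fam_den.sum() != sub.n_total.sum():
                raise RatesError("aggregation inconsistency")  # pragma: no cover
            for group in [OVERALL, *table.families()]:
                pct = aggregate_rate(table, group, marker)
                lines.append(f"rates\t{level}\t{group}\t-\t{marker}\t{pct}")
    return "\n".join(lines) + "\n"
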