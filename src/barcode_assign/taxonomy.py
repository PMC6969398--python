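"""Parsing, canonicalization and comparison of taxonomic labels.

Match calling in barcode assignment reduces to label comparison: a query
is correctly assigned when its binomial (species level) or genus (genus
level) equals that of the best database hit.  Comparisons here are
case-insensitive and treat underscores and spaces as the same character,
because reference headers routinely canonicalize ``Festuca pratensis`` to
``Festuca_pratensis``.  A small correction map fixes misspelled names
before comparison (e.g. ``Arrhenaterum`` -> ``Arrhenatherum``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping

from .errors import TaxonomyError

#: Tokens that introduce an infraspecific rank (or mark an undetermined
#: epithet) rather than a species epithet.  Compared without trailing dot.
RANK_MARKERS = frozenset({
    "var", "subsp", "ssp", "subvar", "f", "forma", "cv",
    "sp", "spp", "cf", "aff",
})


def _norm(name: str) -> str:
    return name.replace("_", " ").strip().lower()


@dataclass(frozen=True)
class TaxonLabel:
    """A parsed taxonomic label: genus, optional epithet, optional family.

    Equality-like comparisons go through :func:`same_species` and
    :func:`same_genus`, which are case-insensitive and underscore/space
    insensitive.
    """

    genus: str
    species_epithet: str | None = None
    family: str | None = None
    infraspecific: str | None = None

    def __post_init__(self) -> None:
        if not self.genus or not self.genus[0].isalpha():
            raise TaxonomyError(f"invalid genus name {self.genus!r}")

    def binomial(self) -> str | None:
        """``Genus epithet`` when an epithet is present, else None."""
        if self.species_epithet is None:
            return None
        return f"{self.genus} {self.species_epithet}"


def parse_taxon(raw: str) -> TaxonLabel:
    """Parse a free-text taxonomy string into a :class:`TaxonLabel`.

    Tokens are split on spaces and underscores.  The first token becomes
    the genus (capitalized); the second becomes the species epithet
    unless it is an infraspecific rank marker ("var.", "subsp.", ...) or
    an undetermined-species marker ("sp.", "cf.", "aff."), in which case
    it and everything after it land in ``infraspecific``.
    """
    if raw is None or not _norm(raw):
        raise TaxonomyError("empty taxonomy string")
    tokens = [t for t in raw.replace("_", " ").split() if t]
    if not any(ch.isalpha() for ch in tokens[0]):
        raise TaxonomyError(f"taxonomy string {raw!r} has no alphabetic genus token")
    genus = tokens[0].capitalize()
    epithet = None
    infra = None
    rest = tokens[1:]
    if rest:
        first = rest[0].rstrip(".").lower()
        if first in RANK_MARKERS:
            infra = " ".join(rest)
        else:
            epithet = rest[0].lower()
            if len(rest) > 1:
                infra = " ".join(rest[1:])
    return TaxonLabel(genus=genus, species_epithet=epithet, infraspecific=infra)


class CorrectionMap:
    """Misspelling corrections applied to genus names and binomials.

    Keys and values may be genus names or space-separated binomials.
    The map is validated to be idempotent: no corrected form is itself a
    key mapping to a different name.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        for wrong, right in (mapping or {}).items():
            self._map[_norm(wrong)] = right.replace("_", " ").strip()
        for right in list(self._map.values()):
            target = self._map.get(_norm(right))
            if target is not None and _norm(target) != _norm(right):
                raise TaxonomyError(
                    f"correction map is not idempotent: {right!r} -> {target!r}"
                )

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, name: str) -> str | None:
        return self._map.get(_norm(name))

    @classmethod
    def from_tsv(cls, path) -> "CorrectionMap":
        """Load a two-column (wrong<TAB>right) file; a header row is allowed."""
        mapping = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TaxonomyError(
                        f"{path}: line {lineno}: expected 2 tab-separated "
                        f"columns, got {len(parts)}"
                    )
                if lineno == 1 and parts[0].lower() in ("wrong", "from"):
                    continue
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    @classmethod
    def default(cls) -> "CorrectionMap":
        """The packaged default corrections (orthographic variants only)."""
        with resources.as_file(
            resources.files("barcode_assign.data").joinpath("corrections.tsv")
        ) as p:
            return cls.from_tsv(p)


def correct(label: TaxonLabel, corrections: CorrectionMap) -> TaxonLabel:
    """Rewrite a label through the correction map; unmapped names pass through.

    Binomial-level corrections take precedence over genus-level ones.
    Applying the function twice equals applying it once.
    """
    binomial = label.binomial()
    if binomial is not None:
        fixed = corrections.lookup(binomial)
        if fixed is not None:
            tokens = fixed.split()
            if len(tokens) != 2:
                raise TaxonomyError(
                    f"binomial correction {binomial!r} -> {fixed!r} is not a binomial"
                )
            return replace(
                label, genus=tokens[0].capitalize(), species_epithet=tokens[1].lower()
            )
    fixed_genus = corrections.lookup(label.genus)
    if fixed_genus is not None:
        return replace(label, genus=fixed_genus.capitalize())
    return label


def same_genus(a: TaxonLabel, b: TaxonLabel) -> bool:
    """Genus-level equality (case- and underscore/space-insensitive)."""
    return _norm(a.genus) == _norm(b.genus)


def same_species(a: TaxonLabel, b: TaxonLabel) -> bool:
    """Species-level (binomial) equality; labels without an epithet never match."""
    ba, bb = a.binomial(), b.binomial()
    if ba is None or bb is None:
        return False
    return _norm(ba) == _norm(bb)


def correct_all(
    labels: Iterable[TaxonLabel], corrections: CorrectionMap
) -> list[TaxonLabel]:
    return [correct(lab, corrections) for lab in labels]
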