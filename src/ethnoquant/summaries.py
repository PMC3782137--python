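"""Descriptive tabulations of a use-report survey.

Reproduces the standard headline numbers of an ethnomedicinal survey
report: distinct species by organism kind, per-disorder species counts
and their share of all species, the most-mentioned species and the
share of all use reports they account for, and inventories of used
parts and preparation methods per kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .indices import round_half_away
from .survey_io import SurveyTable

__all__ = [
    "SurveySummary",
    "summarize",
    "mention_share",
    "top_k_by_mentions",
    "count_practices",
]


@dataclass(frozen=True)
class SurveySummary:
    """Headline tabulations of one survey."""

    total_species: int
    total_mentions: int
    species_by_kind: dict[str, int]
    #: disorder -> (distinct species count, percentage of all species)
    disorder_species_share: dict[str, tuple[int, float]]
    #: ranked (species, kind, total mentions)
    top_mentioned: list[tuple[str, str, int]]
    #: kind -> number of distinct used-part labels
    part_inventory: dict[str, int]
    #: kind -> number of distinct preparation labels
    preparation_inventory: dict[str, int]


def top_k_by_mentions(
    table: SurveyTable, kind: str | None = None, k: int = 3
) -> list[tuple[str, str, int]]:
    """The ``k`` most-mentioned species, optionally restricted to a kind.

    Sorted by total mentions descending, ties broken by canonical name
    ascending.  If fewer than ``k`` species qualify, all are returned.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    totals = table.species_mentions()
    kinds = table.species_kind()
    items = [
        (name, kinds[name], total)
        for name, total in totals.items()
        if kind is None or kinds[name] == kind
    ]
    items.sort(key=lambda t: (-t[2], t[0]))
    return items[:k]


def mention_share(
    table: SurveyTable, species: list[str] | set[str], exact: bool = False
) -> float | Fraction:
    """Percentage of all use reports contributed by the named species.

    Sums the species' mentions across all disorders and divides by the
    survey's total mentions.  Returns the display value rounded
    half-away-from-zero to 2 decimals, or the exact rational when
    ``exact=True``.

    Raises
    ------
    LookupError
        If a named species is absent from the table.
    """
    totals = table.species_mentions()
    missing = [s for s in species if s not in totals]
    if missing:
        raise LookupError(f"species not in table: {missing}")
    share = Fraction(sum(totals[s] for s in set(species)) * 100, table.total_mentions)
    return share if exact else round_half_away(share, 2)


def summarize(table: SurveyTable, top_k: int = 3) -> SurveySummary:
    """Compute all headline tabulations for a survey.

    Percentages are rounded half-away-from-zero to 1 decimal.
    """
    kinds = table.species_kind()
    total_species = len(kinds)
    species_by_kind: dict[str, int] = {}
    for kind in kinds.values():
        species_by_kind[kind] = species_by_kind.get(kind, 0) + 1

    disorder_species: dict[str, set[str]] = {}
    for rec in table.records:
        disorder_species.setdefault(rec.disorder, set()).add(rec.scientific_name)
    disorder_species_share = {
        d: (
            len(s),
            round_half_away(Fraction(len(s) * 100, total_species), 1),
        )
        for d, s in disorder_species.items()
    }

    parts: dict[str, set[str]] = {}
    preps: dict[str, set[str]] = {}
    for rec in table.records:
        parts.setdefault(rec.kind, set()).update(rec.used_parts)
        preps.setdefault(rec.kind, set()).update(rec.preparations)

    return SurveySummary(
        total_species=total_species,
        total_mentions=table.total_mentions,
        species_by_kind=species_by_kind,
        disorder_species_share=disorder_species_share,
        top_mentioned=top_k_by_mentions(table, k=top_k),
        part_inventory={k: len(v) for k, v in parts.items()},
        preparation_inventory={k: len(v) for k, v in preps.items()},
    )


def count_practices(table: SurveyTable) -> dict[str, int]:
    """Experimental count of distinct "ethnomedicinal practices" per kind.

    Survey reports sometimes headline a number of recorded practices,
    counting each distinct remedy (a species used in a particular way)
    once.  That counting unit is not recoverable from a table aggregated
    to (disorder, species) rows: this function counts distinct
    (species, disorder, preparation) triples as its stated, documented
    definition.  Treat the result as a rough inventory, not a statistic
    comparable across differently-aggregated sources.
    """
    triples: dict[str, set[tuple[str, str, str]]] = {}
    for rec in table.records:
        for prep in rec.preparations:
            triples.setdefault(rec.kind, set()).add(
                (rec.scientific_name, rec.disorder, prep)
            )
    counts = {k: len(v) for k, v in triples.items()}
    counts["total"] = sum(counts.values())
    return counts
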