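"""Informant consensus and fidelity-level indices.

Two classical quantitative-ethnobotany statistics:

* Informant Consensus Factor, per ailment category::

      ICF = (n_ur - n_t) / (n_ur - 1)

  where ``n_ur`` is the number of use reports for the category (the sum
  of the mentions column over its records) and ``n_t`` the number of
  distinct species cited for it.  ICF is 1 when every report cites the
  same single species, 0 when every report cites a different species,
  and undefined for a single report (the denominator vanishes).

* Fidelity Level, per (species, disorder) pair::

      FL(%) = N_p * 100 / N

  where ``N_p`` is the number of informants citing the species for that
  particular disorder and ``N`` the number citing it for any disorder.
  FL is 100% exactly when the species is recorded for a single disorder.

Both indices are ratios of small integer counts, so they are kept as
exact :class:`fractions.Fraction` values; display values round
half-away-from-zero (2 decimals for ICF, 1 for FL), matching the usual
reporting convention.  Boundary classifications such as the FL = 100%
census are decided on the exact values, never on rounded floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .survey_io import SurveyTable

__all__ = [
    "DisorderConsensus",
    "SpeciesFidelity",
    "FLCensus",
    "FLDiscrepancy",
    "compute_icf",
    "compute_fl",
    "fl_100_census",
    "audit_printed_fl",
    "round_half_away",
]


def round_half_away(value: Fraction | int, ndigits: int) -> float:
    """Round a non-negative exact rational half-away-from-zero.

    Python's builtin ``round`` uses banker's rounding; survey reports
    conventionally round 0.005 up, so this helper floors
    ``value * 10**ndigits + 1/2`` exactly and rescales.
    """
    q = Fraction(value) * 10**ndigits
    if q < 0:
        raise ValueError("expected a non-negative value")
    scaled = (2 * q.numerator + q.denominator) // (2 * q.denominator)
    return float(scaled) / 10**ndigits


@dataclass(frozen=True)
class DisorderConsensus:
    """Per-disorder use-report bookkeeping and consensus factor.

    ``icf_exact`` is ``None`` when the disorder has a single use report
    (the index is undefined there, not zero).
    """

    disorder: str
    n_ur: int
    n_t: int
    icf_exact: Fraction | None

    @property
    def defined(self) -> bool:
        return self.icf_exact is not None

    @property
    def icf(self) -> float | None:
        """Display value, rounded half-away-from-zero to 2 decimals."""
        if self.icf_exact is None:
            return None
        return round_half_away(self.icf_exact, 2)


@dataclass(frozen=True)
class SpeciesFidelity:
    """Fidelity level of one species for one disorder."""

    scientific_name: str
    disorder: str
    n_p: int
    n_total: int
    fl_exact: Fraction

    @property
    def fl(self) -> float:
        """Display value in percent, rounded half-away-from-zero to 1 decimal."""
        return round_half_away(self.fl_exact, 1)

    @property
    def is_exclusive(self) -> bool:
        """True when the species' reports all concern this disorder (FL = 100)."""
        return self.fl_exact == 100


def compute_icf(table: SurveyTable) -> list[DisorderConsensus]:
    """Compute the informant consensus factor for every disorder.

    Disorders appear in order of first appearance in the table.  An
    empty table yields an empty list.
    """
    order = table.disorders
    n_ur = {d: 0 for d in order}
    species: dict[str, set[str]] = {d: set() for d in order}
    for rec in table.records:
        n_ur[rec.disorder] += rec.mentions
        species[rec.disorder].add(rec.scientific_name)
    out = []
    for disorder in order:
        ur, nt = n_ur[disorder], len(species[disorder])
        icf = Fraction(ur - nt, ur - 1) if ur > 1 else None
        out.append(DisorderConsensus(disorder, ur, nt, icf))
    return out


def compute_fl(table: SurveyTable) -> list[SpeciesFidelity]:
    """Compute the fidelity level for every (species, disorder) record.

    The denominator ``N`` is the species' mention total across the whole
    table (all disorders), which is what makes FL an exclusivity measure
    rather than a within-disorder share.  Results follow table row order.
    """
    totals = table.species_mentions()
    return [
        SpeciesFidelity(
            scientific_name=rec.scientific_name,
            disorder=rec.disorder,
            n_p=rec.mentions,
            n_total=totals[rec.scientific_name],
            fl_exact=Fraction(rec.mentions * 100, totals[rec.scientific_name]),
        )
        for rec in table.records
    ]


@dataclass(frozen=True)
class FLCensus:
    """Count of species with exact FL = 100%, per disorder and overall."""

    per_disorder: dict[str, int]
    total: int


def fl_100_census(fidelities: list[SpeciesFidelity]) -> FLCensus:
    """Count species whose fidelity is exactly 100%, per disorder.

    Equality with 100 is tested on the exact rational value.  A species
    with FL = 100 is by construction recorded for a single disorder, so
    the per-disorder counts partition the censused species and their sum
    equals the overall count.
    """
    per: dict[str, int] = {}
    seen: list[str] = []
    total = 0
    for f in fidelities:
        per.setdefault(f.disorder, 0)
        if f.is_exclusive:
            per[f.disorder] += 1
            if f.scientific_name not in seen:
                seen.append(f.scientific_name)
                total += 1
    return FLCensus(per_disorder=per, total=total)


@dataclass(frozen=True)
class FLDiscrepancy:
    """A printed fidelity level that disagrees with recomputation."""

    scientific_name: str
    disorder: str
    printed: float
    recomputed: float


def audit_printed_fl(
    table: SurveyTable,
    fidelities: list[SpeciesFidelity] | None = None,
    tolerance: float = 0.05,
) -> list[FLDiscrepancy]:
    """Compare printed FL values carried by the table with recomputation.

    A record is flagged when ``|printed - recomputed display value|``
    exceeds ``tolerance`` (percentage points).  Records without a
    printed value are skipped.  On the packaged Korean survey this
    surfaces the two Plantago asiatica rows, whose printed 100.0 cannot
    hold simultaneously for two disorders (each recomputes to 50.0).
    """
    if fidelities is None:
        fidelities = compute_fl(table)
    by_key = {(f.disorder, f.scientific_name): f for f in fidelities}
    out = []
    for rec in table.records:
        if rec.fl_printed is None:
            continue
        f = by_key[(rec.disorder, rec.scientific_name)]
        if abs(rec.fl_printed - f.fl) > tolerance:
            out.append(
                FLDiscrepancy(rec.scientific_name, rec.disorder, rec.fl_printed, f.fl)
            )
    return out
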