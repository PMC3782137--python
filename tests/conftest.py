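"""Shared fixtures and independent oracles.

The oracles here recompute the consensus and fidelity indices from a
fully expanded list of individual reports (one entry per informant
mention) and the one-mode projection from brute-force pairwise
neighborhood intersection.  They deliberately share no code with the
package implementation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from ethnoquant import SurveyTable, UseRecord, load_fixture


@pytest.fixture(scope="session")
def survey() -> SurveyTable:
    """The packaged Korean liver-disorder survey (121 records)."""
    return load_fixture()


# ---------------------------------------------------------------- oracles


def expand_reports(table: SurveyTable) -> list[tuple[str, str]]:
    """One (disorder, species) entry per individual informant report."""
    out = []
    for rec in table.records:
        out.extend([(rec.disorder, rec.scientific_name)] * rec.mentions)
    return out


def oracle_icf(table: SurveyTable) -> dict[str, Fraction | None]:
    """Consensus factor recounted from the expanded report list."""
    reports = expand_reports(table)
    disorders = {d for d, _ in reports}
    out: dict[str, Fraction | None] = {}
    for d in disorders:
        mine = [s for dd, s in reports if dd == d]
        n_ur, n_t = len(mine), len(set(mine))
        out[d] = Fraction(n_ur - n_t, n_ur - 1) if n_ur > 1 else None
    return out


def oracle_fl(table: SurveyTable) -> dict[tuple[str, str], Fraction]:
    """Fidelity level recounted from the expanded report list."""
    reports = expand_reports(table)
    out: dict[tuple[str, str], Fraction] = {}
    for d, s in set(reports):
        n_p = sum(1 for dd, ss in reports if dd == d and ss == s)
        n = sum(1 for _, ss in reports if ss == s)
        out[(s, d)] = Fraction(n_p * 100, n)
    return out


def oracle_projection(
    neighborhoods: dict[str, set[str]]
) -> dict[frozenset[str], int]:
    """Pairwise shared-neighbor counts for one node class."""
    nodes = sorted(neighborhoods)
    out: dict[frozenset[str], int] = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            shared = len(neighborhoods[a] & neighborhoods[b])
            if shared:
                out[frozenset({a, b})] = shared
    return out


# ------------------------------------------------- random small tables


def random_table(rng: np.random.Generator) -> SurveyTable:
    """A random small valid survey (<= 6 disorders, <= 20 species)."""
    n_disorders = int(rng.integers(1, 7))
    n_species = int(rng.integers(1, 21))
    species = [f"Taxon random {i:02d} Test." for i in range(n_species)]
    kinds = rng.choice(["plant", "animal", "fungus"], size=n_species)
    records = []
    for d in range(n_disorders):
        size = int(rng.integers(1, n_species + 1))
        chosen = rng.choice(n_species, size=size, replace=False)
        for i in chosen:
            records.append(
                UseRecord(
                    disorder=f"ailment {d}",
                    scientific_name=species[i],
                    mentions=int(rng.integers(1, 11)),
                    kind=str(kinds[i]),
                    used_parts=frozenset({"whole part"}),
                    preparations=frozenset({"decoction"}),
                )
            )
    return SurveyTable(records=records, name_aliases={})
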