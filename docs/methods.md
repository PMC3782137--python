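# Methods

## Data model

The atomic object is the use-report record: one (disorder, species)
pair with a positive integer mention count (each mention = one
informant's report), the species' organism kind (plant / animal /
fungus), non-empty sets of used parts and preparation labels, an
administration route (oral / topical), and an optional `fl_printed`
column holding a fidelity percentage as printed in a source document.
`fl_printed` is audit-only: no computation ever reads it, so a survey
whose printed column is wrong cannot contaminate the recomputed
indices.  A `SurveyTable` enforces unique (disorder, species) pairs and
canonical scientific names at construction.

Species identity is the full scientific name *including* the author
string, after normalization.  Infraspecific taxa (e.g. *Bupleurum
falcatum* L. vs. *B. falcatum* var. *scorzoneraefolium*) are distinct
species, matching how field surveys count them.  Normalization
collapses whitespace and applies an alias table; the default table
covers the orthographic variants present in the packaged survey
(*mutilan*/*mutilans*; author-string spacing such as
"L.W.Medicus"/"L. W. Medicus").  Without these aliases the
distinct-species count of the packaged survey would be inflated.
Disorder labels matching one of the seven liver-disorder categories
case-insensitively are stored in canonical spelling; other labels pass
through verbatim, so arbitrary surveys load unchanged.

The data model is plain stdlib dataclasses with explicit validation in
`__post_init__` and the readers.  The error contract (schema errors
naming the missing column, row-indexed validation errors) is what
matters here, and it is easier to keep exact with hand-written checks
than behind a validation framework.

Set-valued columns are serialized comma-separated inside one quoted
CSV cell and split/trimmed on read; writing then reading a validated
table is the identity, record for record.

## Indices

ICF = (n_ur − n_t)/(n_ur − 1) per disorder, with n_ur the sum of the
mentions column over the disorder's records and n_t its count of
distinct species.  For n_ur ≤ 1 the index is reported as *undefined*
rather than silently substituted with 0 or 1, since the formula divides
by zero there and either substitution would corrupt cross-category
comparisons.

FL(%) = N_p·100/N per (species, disorder) record, with N_p the record's
mentions and N the species' mentions summed over *all* disorders.  The
whole-table denominator is what makes FL an exclusivity measure; a
within-disorder denominator would pin every value at 100.

Both indices are ratios of small integers and are kept as
`fractions.Fraction`.  Display values round half-away-from-zero (ICF to
2 decimals, FL to 1), the convention survey reports use; Python's
builtin banker's rounding would, e.g., turn an exact 0.855 into 0.85.
The FL = 100% census tests equality on the exact rational, never on a
rounded float, so boundary species cannot be misclassified.

The audit operation compares `fl_printed` against the recomputed
display value with a configurable tolerance (default 0.05 percentage
points, i.e. anything beyond last-digit rounding).  On the packaged
survey it flags exactly the two *Plantago asiatica* rows: the species
has 2 mentions in hepatitis and 2 in jaundice, so each exact FL is 50,
yet both rows carry a printed 100.0 — an impossibility under the
definition.  The recomputed value is treated as authoritative, which is
why the jaundice FL-100 census counts 16 species, not 17.

## Network analysis

The survey induces a two-mode graph: disorder nodes, species nodes
(kind attached as a node attribute, keeping the graph strictly
two-mode), and one edge per record weighted by its mention count.  The
edge weights are a superset of what an unweighted incidence analysis
needs: unweighted degree answers "how many disorders does this species
treat", while the weights make species strength equal the species'
total mentions (a cross-module conservation law the tests enforce) and
enrich the exports.  One-mode projections (networkx's weighted
projection) link two nodes of a class when they share a neighbor, with
the shared-neighbor count as weight; the tests check them against a
brute-force pairwise-intersection oracle.  Exports are GraphML
(attribute-preserving, round-trip tested) and a plain three-column edge
list.  No layout computation: drawing is a job for external viewers.

Per-disorder kind composition reports the neighbor counts by kind, the
modal kind, and every neighbor departing from it.  On the packaged
survey, fatigue recovery's neighborhood is purely animal, while liver
cirrhosis's animal-dominated neighborhood has three departures:
*Bupleurum falcatum* L. (plant), *Fomes fomentarius* (fungus), and
*Oenanthe javanica* (plant, 2 mentions).  The survey's narrative names
only the first two; the package reports what the table yields.

## Summaries

Distinct species by kind, per-disorder species counts with their share
of all species, the top-k species by total mentions (ties by name), and
the share of all use reports contributed by a named species subset
(exact fraction retained; display to 2 decimals).  Used-part and
preparation inventories count distinct labels per kind.

One printed percentage in the source report is internally inconsistent:
59 of 94 species is exactly 62.766%, displayed here as 62.8, while the
report prints 62.7 despite rounding 25/94 = 26.596% to 26.6 in the same
sentence.  The recomputed display is asserted in the tests and the slip
is documented rather than imitated.

A "number of ethnomedicinal practices" headline (counting each distinct
remedy once) cannot be reconstructed from a table aggregated to
(disorder, species) rows.  `count_practices` is therefore explicitly
experimental: it counts distinct (species, disorder, preparation)
triples, states that definition in its docstring, and is excluded from
every headline path.  Family/genus tallies are computed only when the
user supplies a species→(family, genus) mapping; no taxonomy is
bundled.

## Synthetic surveys

The generator emulates a multi-ailment survey with one consensus knob.
Scheme: species are assigned kinds by `kind_probs` and a home disorder
round-robin over the pool (guaranteeing each disorder at least one
eligible species; a pool smaller than the disorder count is a
configuration error); each species is independently a generalist
(eligible for every disorder) with probability `multi_use_prob`, which
is what produces fidelity levels below 100%.  Per disorder, citation
probabilities over the eligible set are symmetric
Dirichlet(`concentration`) and the disorder's reports are multinomial;
species with at least one report become records, with usage metadata
drawn from fixed label vocabularies.  All randomness flows from one
named seeded generator; identical config and seed give a byte-identical
table.

Dirichlet-multinomial allocation is the smallest model whose single
parameter spans ICF's full range: concentration → 0 piles all reports
on one species (ICF → 1), concentration → ∞ spreads them evenly
(ICF → 0 once reports ≤ species).  `expected_icf_curve` exhibits this
monotone diagnostic by simulation.

Defaults mirror the packaged survey's scale: 7 disorders, 94 species
with a 0.61/0.36/0.03 kind split, 216 reports per disorder (≈1,514
total), concentration 0.3 (mean consensus in the observed 0.6–0.95
band), and multi_use_prob 0.2 (18 of the 94 observed species span more
than one disorder).  What the generator does *not* emulate: informant
covariates, correlated part/preparation usage, heavy-tailed species
popularity beyond what the Dirichlet provides, and disorder-specific
report budgets.  Passing tests on synthetic data therefore demonstrate
correctness of the bookkeeping and the indices' behavior across the
consensus range, not realism of any particular field survey.

## Numerical and testing choices

Exact rational arithmetic everywhere an index or boundary decision is
made; floats only at display.  Randomized tests use fixed seeds
(property checks over 200 random small tables per run); the
index implementations are verified against an independent oracle that
expands every record into individual reports and recounts from scratch,
and the projection against brute-force neighborhood intersection.
Monte-Carlo checks (generator calibration, consensus-vs-concentration
monotonicity) use modest sizes — 3 disorders, pools of 30–50, 60–100
reports, 100–200 replicates — chosen so the whole suite runs in a few
seconds while leaving the sampling error well below the asserted
margins (mean comparisons use two combined standard errors).

## Known limitations

- The consensus factor is undefined (not zero) for single-report
  categories; downstream consumers must handle the flag.
- Kind is assumed consistent per species; a species recorded with two
  kinds is a validation error, not a resolvable ambiguity.
- No inferential statistics: ICF and FL are descriptive, and the
  package deliberately stops short of confidence intervals or tests.
- Scientific-name handling is string normalization plus aliases; there
  is no taxonomic-backbone resolution, by design.
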