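"""Two-mode disorder-species network analysis.

The survey induces a bipartite graph: one node per disorder category,
one per medicinal species (carrying its organism kind as an attribute),
and one edge per use-report record, weighted by the mention count.
This module builds that graph, answers the standard two-mode questions
(species degree = number of disorders treated, per-disorder kind
composition), computes weighted one-mode projections (shared-neighbor
counts), and exports to GraphML or a plain edge list for external
network viewers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from networkx.algorithms import bipartite as nx_bipartite

from .survey_io import SurveyTable

__all__ = [
    "BipartiteNetwork",
    "KindComposition",
    "build_network",
    "species_degree",
    "ranked_species_degree",
    "disorder_kind_composition",
    "project_one_mode",
    "export_graph",
    "import_graphml",
]


@dataclass
class BipartiteNetwork:
    """A two-mode disorder-species graph.

    Wraps a :class:`networkx.Graph` whose nodes carry ``mode``
    (``"disorder"`` or ``"species"``) and, for species, ``kind``;
    edges carry integer ``weight`` equal to the mention count.
    """

    graph: nx.Graph

    @property
    def disorder_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["mode"] == "disorder"}

    @property
    def species_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["mode"] == "species"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_bipartite(self) -> bool:
        """2-colorability check consistent with the mode partition."""
        if not nx.is_bipartite(self.graph):
            return False
        return all(
            self.graph.nodes[u]["mode"] != self.graph.nodes[v]["mode"]
            for u, v in self.graph.edges
        )

    def species_strength(self) -> dict[str, int]:
        """Sum of edge weights per species (equals its mention total)."""
        return {
            s: sum(d["weight"] for _, _, d in self.graph.edges(s, data=True))
            for s in self.species_nodes
        }


def build_network(table: SurveyTable) -> BipartiteNetwork:
    """Build the two-mode network from a validated survey table.

    One node per disorder, one per canonical species, one weighted edge
    per record; hence edge count equals record count.  A label shared by
    a disorder and a species would collapse two nodes, so it is rejected.
    """
    g = nx.Graph()
    disorders = set(table.disorders)
    kinds = table.species_kind()
    clash = disorders & set(kinds)
    if clash:
        raise ValueError(f"labels used as both disorder and species: {sorted(clash)}")
    for d in table.disorders:
        g.add_node(d, mode="disorder", bipartite=0)
    for s, kind in kinds.items():
        g.add_node(s, mode="species", bipartite=1, kind=kind)
    for rec in table.records:
        g.add_edge(rec.disorder, rec.scientific_name, weight=rec.mentions)
    return BipartiteNetwork(g)


def species_degree(net: BipartiteNetwork) -> dict[str, int]:
    """Number of distinct disorders each species treats (unweighted degree)."""
    return {s: net.graph.degree(s) for s in net.species_nodes}


def ranked_species_degree(net: BipartiteNetwork) -> list[tuple[str, int]]:
    """Species ranked by degree descending.

    Ties break by total mention weight descending, then name ascending.
    """
    strength = net.species_strength()
    degree = species_degree(net)
    return sorted(
        degree.items(), key=lambda kv: (-kv[1], -strength[kv[0]], kv[0])
    )


@dataclass(frozen=True)
class KindComposition:
    """Kind make-up of one disorder's species neighborhood.

    ``exceptions`` lists the (species, kind) neighbors that are not of
    the modal kind, i.e. the departures from the disorder's dominant
    organism kingdom.
    """

    disorder: str
    counts: dict[str, int]
    modal_kind: str
    exceptions: list[tuple[str, str]]


def disorder_kind_composition(net: BipartiteNetwork) -> dict[str, KindComposition]:
    """Per-disorder counts of neighboring species by organism kind.

    The modal kind is the most frequent among neighbors (ties broken
    alphabetically for determinism); every neighbor of another kind is
    reported as an exception.
    """
    out: dict[str, KindComposition] = {}
    for d in net.disorder_nodes:
        neighbors = list(net.graph.neighbors(d))
        counts = Counter(net.graph.nodes[s]["kind"] for s in neighbors)
        modal = min(counts, key=lambda k: (-counts[k], k))
        exceptions = sorted(
            (s, net.graph.nodes[s]["kind"])
            for s in neighbors
            if net.graph.nodes[s]["kind"] != modal
        )
        out[d] = KindComposition(d, dict(counts), modal, exceptions)
    return out


def project_one_mode(net: BipartiteNetwork, mode: str) -> nx.Graph:
    """Project the two-mode graph onto one node class.

    Two nodes of the chosen mode are linked when they share at least one
    neighbor in the other mode; the edge weight is the number of shared
    neighbors (e.g. species-mode weight between A and B = number of
    disorders treating both).
    """
    if mode not in {"species", "disorder"}:
        raise ValueError(f"mode must be 'species' or 'disorder', got {mode!r}")
    nodes = net.species_nodes if mode == "species" else net.disorder_nodes
    projected = nx_bipartite.weighted_projected_graph(net.graph, nodes)
    # weighted_projected_graph already counts shared neighbors; keep only
    # positive-weight edges (it emits none with weight 0).
    return projected


def export_graph(
    graph: BipartiteNetwork | nx.Graph, path: str | Path, format: str = "graphml"
) -> None:
    """Write a graph as GraphML (attribute-preserving) or an edge list.

    The edge list is whitespace-delimited ``source target weight`` with
    labels containing spaces quoted; GraphML round-trips node and edge
    attributes (``mode``, ``kind``, ``weight``).
    """
    g = graph.graph if isinstance(graph, BipartiteNetwork) else graph
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, d in g.edges(data=True):
                w = d.get("weight", 1)
                fh.write(f'"{u}"\t"{v}"\t{w}\n')
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'edgelist'")


def import_graphml(path: str | Path) -> nx.Graph:
    """Re-import a GraphML file written by :func:`export_graph`."""
    return nx.read_graphml(path)
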