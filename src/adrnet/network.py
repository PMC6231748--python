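"""Lift-weighted heterogeneous network and disease-ADR metapath scores.

The network has three node types (drug, disease, ADR) and three undirected
link types (drug-ADR, disease-ADR, disease-drug); the weight of a link is
the lift of its two end items, so only defined lifts become links.  The
association between the disease and an ADR is then the unnormalized sum,
over every length-2 disease-drug-ADR path, of the product of the two link
weights — the drug acts as the bridge, and direct disease-ADR links are
kept in the network but deliberately excluded from the path score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .association import LiftScore

LINK_TYPES = {
    frozenset({"drug", "adr"}): "drug-adr",
    frozenset({"disease", "adr"}): "disease-adr",
    frozenset({"disease", "drug"}): "disease-drug",
}


@dataclass
class HeteroNetwork:
    """Typed, weighted, undirected graph backed by :class:`networkx.Graph`.

    Node attribute ``entity_type`` holds the node's type; edge attributes
    ``link_type`` and ``weight`` hold the typed link and its lift weight.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, term: str, entity_type: str) -> None:
        self.graph.add_node(term, entity_type=entity_type)

    def add_link(self, a: str, type_a: str, b: str, type_b: str, weight: float) -> None:
        link_type = LINK_TYPES.get(frozenset({type_a, type_b}))
        if link_type is None:
            raise ValueError(f"no link type for node types ({type_a!r}, {type_b!r})")
        if weight < 0:
            raise ValueError("link weights must be non-negative")
        self.add_node(a, type_a)
        self.add_node(b, type_b)
        self.graph.add_edge(a, b, link_type=link_type, weight=float(weight))

    def nodes(self, entity_type: str | None = None) -> list[str]:
        return [
            n
            for n, d in self.graph.nodes(data=True)
            if entity_type is None or d["entity_type"] == entity_type
        ]

    def node_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            counts[d["entity_type"]] = counts.get(d["entity_type"], 0) + 1
        return counts

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]


@dataclass(frozen=True)
class DiseaseAdrScore:
    """Summed path-weight association between the disease and one ADR.

    ``paths`` records each bridging drug with the disease-drug weight, the
    drug-ADR weight, and their product; ``score`` is the sum of products.
    ``direct_weight`` is the weight of the direct disease-ADR link if any;
    it is reported but never part of the score.
    """

    disease: str
    adr: str
    score: float
    paths: tuple[tuple[str, float, float, float], ...]
    direct_weight: float | None = None


def build_network(
    lifts: Iterable[LiftScore],
    min_weight: float = 0.0,
    nodes: Iterable[tuple[str, str]] = (),
) -> HeteroNetwork:
    """Build the heterogeneous network from defined lift scores.

    One undirected weighted link per defined lift with value strictly above
    ``min_weight`` (default 0 keeps all defined links; 1.0 keeps only
    positively associated pairs).  ``nodes`` adds isolated nodes for terms
    observed in counting but filtered out of every link.
    """
    net = HeteroNetwork()
    for term, etype in nodes:
        net.add_node(term, etype)
    for s in lifts:
        if not s.defined or s.value <= min_weight:
            continue
        net.add_link(s.a, s.types[0], s.b, s.types[1], s.value)
    return net


def disease_adr_scores(
    network: HeteroNetwork, disease: str, normalize: bool = False
) -> list[DiseaseAdrScore]:
    """Score every ADR node by summing disease-drug-ADR path products.

    ``normalize=True`` divides each score by its path count (off by
    default; the unnormalized sum is the model).  ADRs with no bridging
    drug score 0.  Results are sorted by descending score, then ADR name.
    """
    g = network.graph
    if disease not in g or g.nodes[disease]["entity_type"] != "disease":
        raise ValueError(f"disease node {disease!r} not present in network")
    drug_neighbors = [
        n for n in g.neighbors(disease) if g.nodes[n]["entity_type"] == "drug"
    ]
    scores: list[DiseaseAdrScore] = []
    for adr in network.nodes("adr"):
        paths: list[tuple[str, float, float, float]] = []
        for drug in drug_neighbors:
            if g.has_edge(drug, adr):
                w_dr = g.edges[disease, drug]["weight"]
                w_ra = g.edges[drug, adr]["weight"]
                paths.append((drug, w_dr, w_ra, w_dr * w_ra))
        paths.sort(key=lambda p: (-p[3], p[0]))
        score = sum(p[3] for p in paths)
        if normalize and paths:
            score /= len(paths)
        direct = g.edges[disease, adr]["weight"] if g.has_edge(disease, adr) else None
        scores.append(
            DiseaseAdrScore(
                disease=disease, adr=adr, score=score,
                paths=tuple(paths), direct_weight=direct,
            )
        )
    scores.sort(key=lambda s: (-s.score, s.adr))
    return scores


def write_network_tsv(network: HeteroNetwork, path: str | Path) -> None:
    """Edge-list export: type_a, term_a, type_b, term_b, link_type, weight."""
    g = network.graph
    rows = []
    for a, b, d in sorted(g.edges(data=True)):
        rows.append(
            (g.nodes[a]["entity_type"], a, g.nodes[b]["entity_type"], b,
             d["link_type"], d["weight"])
        )
    pd.DataFrame(
        rows, columns=["type_a", "term_a", "type_b", "term_b", "link_type", "weight"]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(network: HeteroNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, path)
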