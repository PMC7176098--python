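"""Confidence scoring of homology inferences and network export.

The confidence score of an inference is ``-N * log10(E)``, where N is the
number of TMSs in the family-linking (B-C) alignment and E its E-value:
more aligned TMSs and a smaller E-value both increase confidence.  Scores
are normalised to the highest-scoring inference *within one run*, so
normalised values are not comparable across runs.  Confidence levels use
fixed bands on the normalised score: high (>= 0.6), medium (0.6 > s >= 0.4)
and low (< 0.4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx

logger = logging.getLogger("tmspath")

LEVEL_HIGH = 0.6
LEVEL_MEDIUM = 0.4


def confidence_score(n_tms: int, evalue: float) -> float:
    """Raw confidence score ``-n_tms * log10(evalue)``.

    ``evalue`` must be in (0, 1]; values above 1 are clamped to score 0
    with a warning (an alignment no better than chance carries no
    confidence).
    """
    if n_tms < 1:
        raise ValueError("n_tms must be >= 1")
    if evalue <= 0:
        raise ValueError("evalue must be positive")
    if evalue > 1:
        logger.warning("E-value %g > 1; confidence clamped to 0", evalue)
        return 0.0
    return -n_tms * math.log10(evalue)


def level_for(norm_score: float) -> str:
    if norm_score >= LEVEL_HIGH:
        return "high"
    if norm_score >= LEVEL_MEDIUM:
        return "medium"
    return "low"


def normalize_and_level(raw_scores: Sequence[float]) -> tuple[list[float], list[str]]:
    """Normalise raw scores by the run maximum and assign confidence levels."""
    if not raw_scores:
        raise ValueError("no scores to normalise")
    top = max(raw_scores)
    if top <= 0:
        raise ValueError("all scores are zero; nothing to normalise")
    norm = [s / top for s in raw_scores]
    return norm, [level_for(s) for s in norm]


def annotate_inferences(inferences):
    """Attach normalised scores and levels to a set of inferences."""
    norm, levels = normalize_and_level([inf.raw_score for inf in inferences])
    return [
        replace(inf, norm_score=n, level=l)
        for inf, n, l in zip(inferences, norm, levels)
    ]


@dataclass(frozen=True)
class FamilyNetwork:
    """Undirected family-relationship network.

    One edge per family pair (the best-scoring inference wins); node
    shading value is the degree.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float, str]]:
        return [
            (a, d, data["norm_score"], data["level"])
            for a, d, data in self.graph.edges(data=True)
        ]


def build_network(inferences) -> FamilyNetwork:
    """Build the family network from scored inferences.

    Inferences must carry ``norm_score`` and ``level`` (see
    :func:`annotate_inferences`); duplicate family pairs keep the higher
    normalised score.
    """
    g = nx.Graph()
    for inf in inferences:
        if inf.norm_score is None or inf.level is None:
            raise ValueError("inferences must be normalised before network export")
        a, d = inf.family_a, inf.family_d
        if g.has_edge(a, d) and g[a][d]["norm_score"] >= inf.norm_score:
            continue
        g.add_edge(a, d, norm_score=inf.norm_score, level=inf.level,
                   raw_score=inf.raw_score)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return FamilyNetwork(g)


def write_edge_tsv(network: FamilyNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# family_a\tfamily_d\traw\tnorm\tlevel\n")
        for a, d, data in network.graph.edges(data=True):
            fh.write(f"{a}\t{d}\t{data['raw_score']:.2f}\t"
                     f"{data['norm_score']:.3f}\t{data['level']}\n")


def write_graphml(network: FamilyNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
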