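"""Bit-score hierarchical clustering of protein sets.

All-vs-all local alignment bit scores are turned into distances
``d(i,j) = 1 - b(i,j) / min(b(i,i), b(j,j))`` (clamped to [0, 1]): identical
sequences are at distance 0 and unrelated pairs near 1.  Agglomerative
nesting with average linkage produces a merge tree whose strength is
summarised by the agglomerative coefficient — the mean over items of
``1 - m(i)/M`` where ``m(i)`` is the dissimilarity at which item i first
merges and M the final merge height.  This is similarity clustering, not
model-based phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import bit_score, raw_score
from .core_io import ProteinRecord, RunConfig


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if d.min() < 0 or d.max() > 1:
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class ClusterTree:
    """Merge structure over labelled items (scipy linkage convention).

    ``merges[r]`` is (left_id, right_id, height); ids below n are leaves,
    id n + r is the cluster created by row r.  ``has_inversions`` flags
    non-monotone merge heights (not expected under average linkage).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    agglomerative_coefficient: float
    has_inversions: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.agglomerative_coefficient <= 1.0):
            raise ValueError("agglomerative coefficient must lie in [0, 1]")

    @property
    def linkage_matrix(self) -> np.ndarray:
        n = len(self.labels)
        z = np.zeros((len(self.merges), 4))
        sizes = {i: 1 for i in range(n)}
        for r, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + r] = size
            z[r] = [a, b, h, size]
        return z

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment at the requested number of clusters."""
        assignment = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))


def bitscore_distance(records: Sequence[ProteinRecord],
                      config: RunConfig | None = None,
                      normalization: str = "min-self") -> DistanceMatrix:
    """All-vs-all bit-score distance matrix.

    ``normalization`` divides the cross bit score by the smaller
    (``"min-self"``, default) or larger (``"max-self"``) of the two
    self-alignment bit scores; min-self makes a perfect substring match
    distance 0.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if normalization not in {"min-self", "max-self"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    config = config or RunConfig()
    n = len(records)
    self_bits = np.empty(n)
    for i, rec in enumerate(records):
        bits = bit_score(raw_score(rec, rec, config), config)
        if bits <= 0:
            raise ValueError(f"{rec.accession}: non-positive self score")
        self_bits[i] = bits
    pick = min if normalization == "min-self" else max
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            bits = bit_score(raw_score(records[i], records[j], config), config)
            denom = pick(self_bits[i], self_bits[j])
            d[i, j] = d[j, i] = float(np.clip(1.0 - bits / denom, 0.0, 1.0))
    return DistanceMatrix(tuple(r.accession for r in records), d)


def agnes_average(dist: DistanceMatrix) -> ClusterTree:
    """Agglomerative nesting with average linkage (UPGMA-style update).

    The agglomerative coefficient is the mean over items of
    ``1 - m(i)/M``; for n = 2 it is 0 by construction.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    z = linkage(squareform(dist.d, checks=False), method="average")
    heights = z[:, 2]
    final = float(heights[-1])
    first_merge = np.zeros(n)
    for row in z:
        for child in (int(row[0]), int(row[1])):
            if child < n:
                first_merge[child] = row[2]
    ac = float(np.mean(1.0 - first_merge / final)) if final > 0 else 0.0
    return ClusterTree(
        labels=dist.labels,
        merges=tuple((int(a), int(b), float(h)) for a, b, h, _ in z),
        agglomerative_coefficient=float(np.clip(ac, 0.0, 1.0)),
        has_inversions=bool(np.any(np.diff(heights) < -1e-12)),
    )


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick string with merge heights encoded as branch lengths.

    A node's branch length is its parent's merge height minus its own
    (leaves sit at height 0), so root-to-leaf path lengths equal the final
    merge height.
    """
    n = len(tree.labels)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for r, (a, b, h) in enumerate(tree.merges):
        height[n + r] = h
        children[n + r] = (a, b)

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{_quote(tree.labels[node])}:{bl:.6g}"
        a, b = children[node]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

    root = n + len(tree.merges) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"


def export_tree(tree: ClusterTree, path, fmt: str = "newick") -> None:
    """Write the merge tree as Newick or Nexus (labels escaped per format)."""
    newick = tree_to_newick(tree)
    if fmt == "newick":
        with open(path, "w") as fh:
            fh.write(newick + "\n")
    elif fmt == "nexus":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.write(path=str(path), schema="nexus")
    else:
        raise ValueError(f"unknown tree format {fmt!r}")


def select_representatives(dist: DistanceMatrix,
                           targets: dict[str, int],
                           families: dict[str, str]) -> list[str]:
    """Greedy max-min diversity picker with per-family target counts.

    Within each family, starts from the item most distant from all others
    and repeatedly adds the item maximising its minimum distance to the
    already-selected set.  A helper for building representative sets; it
    makes no claim of reproducing any particular published selection.
    """
    idx = {lab: i for i, lab in enumerate(dist.labels)}
    chosen: list[str] = []
    for family, count in targets.items():
        members = [lab for lab in dist.labels if families.get(lab) == family]
        if not members:
            continue
        count = min(count, len(members))
        sub = [idx[m] for m in members]
        first = max(sub, key=lambda i: float(np.sum(dist.d[i, sub])))
        picked = [first]
        while len(picked) < count:
            best = max(
                (i for i in sub if i not in picked),
                key=lambda i: min(float(dist.d[i, j]) for j in picked),
            )
            picked.append(best)
        chosen.extend(dist.labels[i] for i in picked)
    return chosen


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# label\t" + "\t".join(dist.labels) + "\n")
        for lab, row in zip(dist.labels, dist.d):
            fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
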