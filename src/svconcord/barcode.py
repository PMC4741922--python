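"""Genomic rearrangement "barcodes": cohort-wide non-redundant event
catalogue, presence/absence matrix, and hierarchical clustering.

Events from all samples are collapsed into non-redundant columns by
single-linkage clustering under the breakpoint matching rule: any two
events matching within the window join the same cluster, so chains can
extend past one window width (accepted, and logged when it happens).
Samples are then clustered on the binary (Jaccard) distance between
their presence/absence rows with Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .compare import MatchWindow
from .model import GenomeModel, Rearrangement, rearrangement_sort_key

log = logging.getLogger("svconcord")


@dataclass
class BarcodeMatrix:
    """Samples x non-redundant rearrangements, cells in {0, 1}.

    ``representatives[k]`` is the member of column k with the median left
    coordinate (lower median on even counts); ``clusters[k]`` holds all
    members.  Columns are ordered by genome position of the
    representative's left breakpoint.
    """

    matrix: pd.DataFrame
    representatives: list[Rearrangement]
    clusters: list[list[Rearrangement]]

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_nonredundant(
    catalogues: dict[str, list[Rearrangement]],
    w: MatchWindow,
    genome: GenomeModel,
) -> BarcodeMatrix:
    """Collapse per-sample catalogues into a presence/absence matrix.

    ``catalogues`` maps sample id -> filtered events.  All events across
    samples are single-linkage clustered under the matching rule; each
    cluster becomes one column and cell (s, c) is 1 iff sample s
    contributed at least one member to cluster c.
    """
    samples = list(catalogues)
    events: list[Rearrangement] = []
    owner: list[str] = []
    for s in samples:
        for r in catalogues[s]:
            events.append(r)
            owner.append(s)
    n = len(events)
    uf = _UnionFind(n)
    by_chrom: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(events):
        by_chrom.setdefault((r.left.chrom, r.right.chrom), []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: events[i].left.pos)
        for a in range(len(idxs)):
            i = idxs[a]
            for b in range(a + 1, len(idxs)):
                j = idxs[b]
                if events[j].left.pos - events[i].left.pos > w.half_width:
                    break
                if abs(events[i].right.pos - events[j].right.pos) <= w.half_width:
                    uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters: list[list[Rearrangement]] = []
    reps: list[Rearrangement] = []
    chained = 0
    for members in groups.values():
        evs = [events[i] for i in members]
        evs.sort(key=lambda r: rearrangement_sort_key(r, genome))
        span = max(e.left.pos for e in evs) - min(e.left.pos for e in evs)
        if span > w.half_width:
            chained += 1
        rep = evs[(len(evs) - 1) // 2]  # member with (lower) median left coordinate
        clusters.append(evs)
        reps.append(rep)
    if chained:
        log.info("barcode: %d cluster(s) chained beyond one window width", chained)

    order = sorted(range(len(reps)), key=lambda k: rearrangement_sort_key(reps[k], genome))
    clusters = [clusters[k] for k in order]
    reps = [reps[k] for k in order]

    # map each event object to its (ordered) column
    root_index: dict[int, int] = {}
    for col, members in enumerate(clusters):
        for ev in members:
            root_index[id(ev)] = col
    mat = np.zeros((len(samples), len(clusters)), dtype=int)
    srow = {s: i for i, s in enumerate(samples)}
    for i, ev in enumerate(events):
        mat[srow[owner[i]], root_index[id(ev)]] = 1
    cols = [f"c{k}" for k in range(len(clusters))]
    return BarcodeMatrix(
        matrix=pd.DataFrame(mat, index=samples, columns=cols),
        representatives=reps,
        clusters=clusters,
    )


def binary_distance(m: BarcodeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Jaccard (asymmetric binary) distance between sample rows:
    d(x, y) = 1 - |x AND y| / |x OR y|; an all-zero union gives 0."""
    df = m.matrix if isinstance(m, BarcodeMatrix) else m
    x = df.to_numpy(dtype=bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def ward_cluster(d: pd.DataFrame) -> np.ndarray:
    """Agglomerative Ward linkage on a precomputed distance matrix.

    Ward assumes Euclidean distances; applying it to a Jaccard matrix is
    a deliberate fidelity choice (the clustering semantics of the
    standard binary-distance + ward recipe), not an oversight.
    """
    condensed = squareform(d.to_numpy(), checks=False)
    return hierarchy.linkage(condensed, method="ward")


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage dendrogram as Newick with merge heights."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return recurse(tree, tree.dist) + ";"
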