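"""Grouping of overlapping biclusters into meta-biclusters.

Mirrors the published four-step procedure: keep biclusters with enough
genes (and, optionally, a trait of interest), score every pair by the
Jaccard similarity of their gene sets, agglomerate with average linkage
(UPGMA) on the distance 1 - Jaccard, cut the tree into k groups, and
summarise each group by its gene union and gene/trait frequency tables.

The main clustering path delegates to scipy's hierarchical clustering; a
plain-loop quadratic UPGMA (`reference_upgma_partitions`) with an explicit
deterministic tie-break is provided as an independent reference for
validation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .bibit import Bicluster, BiclusterSet


def filter_biclusters(
    bset: BiclusterSet,
    min_genes: int = 10,
    required_trait_ids: Iterable[str] = (),
    trait_pattern: str | None = None,
) -> BiclusterSet:
    """Keep biclusters with >= ``min_genes`` genes and a trait of interest.

    Traits of interest may be given as an explicit identifier set and/or a
    regular expression matched against trait identifiers; with neither, no
    trait constraint applies.  A bicluster passes if any of its traits is
    selected by either route.
    """
    required = set(required_trait_ids)
    regex = re.compile(trait_pattern) if trait_pattern else None

    def trait_ok(b: Bicluster) -> bool:
        if not required and regex is None:
            return True
        for i in b.trait_indices:
            tid = bset.trait_ids[i]
            if tid in required or (regex is not None and regex.search(tid)):
                return True
        return False

    kept = [b for b in bset.biclusters if b.n_genes >= min_genes and trait_ok(b)]
    return BiclusterSet(
        biclusters=kept,
        trait_ids=list(bset.trait_ids),
        gene_ids=list(bset.gene_ids),
        params={
            **bset.params,
            "min_genes": min_genes,
            "required_trait_ids": sorted(required),
            "trait_pattern": trait_pattern,
        },
        matrix_digest=bset.matrix_digest,
    )


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise gene-set Jaccard matrix over biclusters."""

    bicluster_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.bicluster_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.bicluster_ids)

    def to_distance(self) -> np.ndarray:
        """Jaccard distance 1 - J with an exactly zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.bicluster_ids) + "\n")
            for bid, row in zip(self.bicluster_ids, self.values):
                fh.write(bid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def pairwise_similarity(bset: BiclusterSet) -> SimilarityMatrix:
    """Jaccard similarity over gene index sets for every bicluster pair."""
    if len(bset) < 2:
        raise ValueError("need at least 2 biclusters for pairwise similarity")
    gene_sets = [set(b.gene_indices) for b in bset.biclusters]
    n = len(gene_sets)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard(gene_sets[i], gene_sets[j])
    return SimilarityMatrix([b.id for b in bset.biclusters], values)


def _canonical_labels(groups: Sequence[Iterable[int]], n: int) -> np.ndarray:
    """Deterministic labels: groups numbered 0..k-1 in ascending order of
    their smallest member index."""
    ordered = sorted((sorted(g) for g in groups), key=lambda g: g[0])
    labels = np.empty(n, dtype=int)
    for gi, members in enumerate(ordered):
        labels[members] = gi
    return labels


def average_linkage_cluster(sim: SimilarityMatrix, k: int) -> np.ndarray:
    """Cut a UPGMA tree on Jaccard distance into exactly k groups.

    Returns an integer label per bicluster (0-based, ordered by each
    group's smallest member index).
    """
    n = len(sim)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n)
    d = sim.to_distance()
    Z = linkage(squareform(d, checks=False), method="average")
    flat = cut_tree(Z, n_clusters=k).ravel()
    groups = [np.flatnonzero(flat == g) for g in np.unique(flat)]
    return _canonical_labels(groups, n)


def reference_upgma_partitions(d: np.ndarray) -> dict[int, list[frozenset[int]]]:
    """Plain-loop UPGMA used only as a validation reference.

    Returns the partition at every cut level k (number of clusters) from n
    down to 1.  Merges greedily by minimum size-weighted average distance;
    exact ties are broken by the smaller, then the larger, of the two
    clusters' smallest original member indices.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    partitions = {n: sorted(clusters.values(), key=min)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for (ci, cj), dij in dist.items():
            lo = min(min(clusters[ci]), min(clusters[cj]))
            hi = max(min(clusters[ci]), min(clusters[cj]))
            key = (dij, lo, hi)
            if best is None or key < best[0]:
                best = (key, ci, cj)
        _, ci, cj = best
        merged = clusters[ci] | clusters[cj]
        size_i, size_j = len(clusters[ci]), len(clusters[cj])
        del clusters[ci], clusters[cj]
        new_dist = {}
        for ck in clusters:
            dik = dist[(min(ci, ck), max(ci, ck))]
            djk = dist[(min(cj, ck), max(cj, ck))]
            new_dist[ck] = (size_i * dik + size_j * djk) / (size_i + size_j)
        dist = {
            (a, b): v
            for (a, b), v in dist.items()
            if ci not in (a, b) and cj not in (a, b)
        }
        clusters[next_id] = merged
        for ck, v in new_dist.items():
            dist[(min(ck, next_id), max(ck, next_id))] = v
        next_id += 1
        partitions[len(clusters)] = sorted(clusters.values(), key=min)
    return partitions


def reference_upgma_labels(d: np.ndarray, k: int) -> np.ndarray:
    """Labels from the reference UPGMA at cut level k (canonical order)."""
    parts = reference_upgma_partitions(d)
    return _canonical_labels([sorted(g) for g in parts[k]], d.shape[0])


@dataclass
class MetaBicluster:
    """A group of biclusters summarised by union and frequency tables."""

    label: str
    member_ids: list[str]
    gene_union: frozenset[str]
    gene_frequency: list[tuple[str, int]]
    trait_frequency: list[tuple[str, int]]

    @property
    def trait_union(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.trait_frequency)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def summarize_meta(bset: BiclusterSet, labels: Sequence[int]) -> list[MetaBicluster]:
    """Per-group member list, gene union, and gene/trait frequency tables.

    Frequencies count how many member biclusters contain each identifier,
    sorted by descending count then identifier.  Labels are rendered as
    ``C1..Ck`` in ascending group order.
    """
    labels = np.asarray(labels)
    if len(labels) != len(bset):
        raise ValueError("labels must cover every bicluster")
    if len(bset) == 0:
        raise ValueError("empty bicluster set")
    metas: list[MetaBicluster] = []
    for g in sorted(set(int(x) for x in labels)):
        members = [b for b, lab in zip(bset.biclusters, labels) if lab == g]
        gene_counts: Counter[str] = Counter()
        trait_counts: Counter[str] = Counter()
        for b in members:
            gene_counts.update(bset.gene_ids[j] for j in b.gene_indices)
            trait_counts.update(bset.trait_ids[i] for i in b.trait_indices)
        metas.append(
            MetaBicluster(
                label=f"C{g + 1}",
                member_ids=[b.id for b in members],
                gene_union=frozenset(gene_counts),
                gene_frequency=sorted(
                    gene_counts.items(), key=lambda kv: (-kv[1], kv[0])
                ),
                trait_frequency=sorted(
                    trait_counts.items(), key=lambda kv: (-kv[1], kv[0])
                ),
            )
        )
    return metas


def write_labels_tsv(
    bset: BiclusterSet, labels: Sequence[int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("bicluster_id\tmeta_label\n")
        for b, lab in zip(bset.biclusters, labels):
            fh.write(f"{b.id}\tC{int(lab) + 1}\n")


def write_meta_summary_tsv(metas: Sequence[MetaBicluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("meta_label\taxis\tidentifier\tfrequency\n")
        for meta in metas:
            for gid, count in meta.gene_frequency:
                fh.write(f"{meta.label}\tgene\t{gid}\t{count}\n")
            for tid, count in meta.trait_frequency:
                fh.write(f"{meta.label}\ttrait\t{tid}\t{count}\n")
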