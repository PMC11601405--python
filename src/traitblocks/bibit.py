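"""BiBit enumeration of all-ones biclusters in a binary trait × gene matrix.

A bicluster is a pair of index sets (traits T, genes G) such that every
cell (i in T, j in G) of the binarized matrix is 1: a rectangle of jointly
significant gene-trait associations.  BiBit seeds candidate gene patterns
from the bitwise AND of every unordered pair of trait rows, then extends
each novel pattern with all rows that contain it.  The enumeration is
exact for the patterns reachable from row pairs and deduplicates on the
gene pattern (the supporting row set is a function of the pattern).

``brute_force_biclusters`` implements the same contract with literal
nested loops and no bit tricks; it exists purely as an independent oracle
for testing and is guarded to small matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .matrix import BinaryMatrix


@dataclass(frozen=True)
class Bicluster:
    """One all-ones rectangle: ordered trait and gene index tuples."""

    id: str
    trait_indices: tuple[int, ...]
    gene_indices: tuple[int, ...]

    @property
    def n_traits(self) -> int:
        return len(self.trait_indices)

    @property
    def n_genes(self) -> int:
        return len(self.gene_indices)


@dataclass
class BiclusterSet:
    """Result of one enumeration run, with label registries and parameters."""

    biclusters: list[Bicluster]
    trait_ids: list[str]
    gene_ids: list[str]
    params: dict
    matrix_digest: str = ""

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def as_index_pairs(self) -> set[tuple[frozenset, frozenset]]:
        """Identity view used to compare runs: set of (trait set, gene set)."""
        return {
            (frozenset(b.trait_indices), frozenset(b.gene_indices))
            for b in self.biclusters
        }

    def trait_labels(self, b: Bicluster) -> list[str]:
        return [self.trait_ids[i] for i in b.trait_indices]

    def gene_labels(self, b: Bicluster) -> list[str]:
        return [self.gene_ids[j] for j in b.gene_indices]

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for b in self.biclusters:
                fh.write(
                    json.dumps(
                        {
                            "id": b.id,
                            "trait_ids": self.trait_labels(b),
                            "gene_ids": self.gene_labels(b),
                            "n_traits": b.n_traits,
                            "n_genes": b.n_genes,
                        }
                    )
                )
                fh.write("\n")

    def write_summary_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tn_traits\tn_genes\n")
            for b in self.biclusters:
                fh.write(f"{b.id}\t{b.n_traits}\t{b.n_genes}\n")


def read_jsonl(path: str | Path) -> BiclusterSet:
    """Load a bicluster set from JSON-lines; registries rebuilt from content."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    trait_ids = sorted({t for r in records for t in r["trait_ids"]})
    gene_ids = sorted({g for r in records for g in r["gene_ids"]})
    t_index = {t: i for i, t in enumerate(trait_ids)}
    g_index = {g: j for j, g in enumerate(gene_ids)}
    bics = [
        Bicluster(
            id=r["id"],
            trait_indices=tuple(sorted(t_index[t] for t in r["trait_ids"])),
            gene_indices=tuple(sorted(g_index[g] for g in r["gene_ids"])),
        )
        for r in records
    ]
    return BiclusterSet(bics, trait_ids, gene_ids, params={})


def run_bibit(matrix: BinaryMatrix, mnr: int = 2, mnc: int = 2) -> BiclusterSet:
    """Enumerate biclusters with the row-pair bit-pattern algorithm.

    Parameters
    ----------
    matrix
        Bit-packed binarized association matrix (traits as rows).
    mnr
        Minimum number of rows (traits) per bicluster, at least 2: a
        pattern is seeded from a pair of rows.
    mnc
        Minimum number of columns (genes) per bicluster, at least 1.

    Every unordered row pair (a, b) proposes the pattern P = row_a AND
    row_b.  If P has at least ``mnc`` set bits and has not been emitted
    before, its support R = {r : row_r AND P == P} is collected; the
    bicluster (R, columns of P) is emitted when |R| >= ``mnr``.  Each gene
    pattern appears at most once in the result.
    """
    if mnr < 2:
        raise ValueError("mnr must be at least 2 (patterns are seeded by row pairs)")
    if mnc < 1:
        raise ValueError("mnc must be at least 1")
    n = matrix.n_traits
    if n < 2 or matrix.n_genes == 0:
        raise ValueError("matrix must have at least 2 rows and 1 column")

    rows = matrix.packed
    popcounts = matrix.row_popcounts()
    # rows too sparse to contain any mnc-column pattern cannot seed one
    seeds = np.flatnonzero(popcounts >= mnc)

    seen: set[bytes] = set()
    out: list[Bicluster] = []
    for ai in range(len(seeds)):
        a = int(seeds[ai])
        partners = seeds[ai + 1 :]
        if partners.size == 0:
            continue
        patterns = rows[a] & rows[partners]
        pattern_sizes = np.bitwise_count(patterns).sum(axis=1, dtype=np.int64)
        for bi in np.flatnonzero(pattern_sizes >= mnc):
            pat = patterns[bi]
            key = pat.tobytes()
            if key in seen:
                continue
            seen.add(key)
            support = np.flatnonzero(np.all((rows & pat) == pat, axis=1))
            if support.size < mnr:
                continue
            cols = np.flatnonzero(
                np.unpackbits(pat, bitorder="little")[: matrix.n_genes]
            )
            out.append(
                Bicluster(
                    id=f"B{len(out):05d}",
                    trait_indices=tuple(int(r) for r in support),
                    gene_indices=tuple(int(c) for c in cols),
                )
            )
    return BiclusterSet(
        biclusters=out,
        trait_ids=list(matrix.trait_ids),
        gene_ids=list(matrix.gene_ids),
        params={"mnr": mnr, "mnc": mnc, "threshold_used": matrix.threshold_used},
        matrix_digest=matrix.digest(),
    )


def brute_force_biclusters(
    matrix: BinaryMatrix, mnr: int = 2, mnc: int = 2
) -> BiclusterSet:
    """Oracle enumeration by literal loops; same contract as ``run_bibit``.

    Guarded to matrices of at most 64 × 64.  Deliberately uses plain
    Python lists and column-by-column comparisons so that it shares no
    machinery with the bit-packed path.
    """
    if matrix.n_traits > 64 or matrix.n_genes > 64:
        raise ValueError("brute-force oracle is limited to 64 x 64 matrices")
    if mnr < 2:
        raise ValueError("mnr must be at least 2")
    if mnc < 1:
        raise ValueError("mnc must be at least 1")
    if matrix.n_traits < 2 or matrix.n_genes == 0:
        raise ValueError("matrix must have at least 2 rows and 1 column")

    dense = [[int(v) for v in row] for row in matrix.to_dense()]
    n = len(dense)
    m = len(dense[0])
    seen_patterns: list[list[int]] = []
    out: list[Bicluster] = []
    for a in range(n):
        for b in range(a + 1, n):
            pattern = [dense[a][j] & dense[b][j] for j in range(m)]
            if sum(pattern) < mnc:
                continue
            if pattern in seen_patterns:
                continue
            seen_patterns.append(pattern)
            support = []
            for r in range(n):
                contains = True
                for j in range(m):
                    if pattern[j] == 1 and dense[r][j] == 0:
                        contains = False
                        break
                if contains:
                    support.append(r)
            if len(support) >= mnr:
                cols = [j for j in range(m) if pattern[j] == 1]
                out.append(
                    Bicluster(
                        id=f"B{len(out):05d}",
                        trait_indices=tuple(support),
                        gene_indices=tuple(cols),
                    )
                )
    return BiclusterSet(
        biclusters=out,
        trait_ids=list(matrix.trait_ids),
        gene_ids=list(matrix.gene_ids),
        params={"mnr": mnr, "mnc": mnc, "threshold_used": matrix.threshold_used},
        matrix_digest=matrix.digest(),
    )


def _cell_jaccard(
    traits_a: Iterable[int],
    genes_a: Iterable[int],
    traits_b: Iterable[int],
    genes_b: Iterable[int],
) -> float:
    """Jaccard index between two rectangles viewed as sets of cells."""
    ta, ga = set(traits_a), set(genes_a)
    tb, gb = set(traits_b), set(genes_b)
    inter = len(ta & tb) * len(ga & gb)
    union = len(ta) * len(ga) + len(tb) * len(gb) - inter
    return inter / union if union else 0.0


def match_score(found: BiclusterSet | Sequence[Bicluster], truth) -> float:
    """Recovery score of planted blocks: mean best cell-Jaccard per block.

    For each truth block, the maximum Jaccard index over found biclusters
    between the two rectangles' cell sets (Cartesian products of trait and
    gene indices) is taken; the score is the mean over truth blocks.
    An empty found set scores 0.0 (as does an empty truth list).
    """
    found_list = list(found)
    truth_list = list(truth)
    if not truth_list or not found_list:
        return 0.0
    total = 0.0
    for block in truth_list:
        total += max(
            _cell_jaccard(
                block.trait_indices, block.gene_indices, b.trait_indices, b.gene_indices
            )
            for b in found_list
        )
    return total / len(truth_list)
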