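"""Trait × gene association matrices and their binarization.

The pipeline consumes a dense matrix ``M`` of association p-values with
traits as rows and genes as columns (in a phenome-wide TWAS setting, one
p-value per gene-trait pair).  Binarization at a significance threshold
``t`` produces the 0/1 matrix ``E`` with ``E[i, j] = 1`` iff
``M[i, j] < t``; all downstream biclustering operates on ``E``.

Rows of ``E`` are bit-packed (8 columns per byte, little-endian bit order
within each byte) so that the pattern-mining stage can use bitwise AND and
popcount; the layout is byte-oriented and therefore identical on every
platform.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Significance threshold used by default for binarization: the study-wide
#: Bonferroni cutoff for a phenome-wide TWAS matrix.  Kept as an explicit
#: constant rather than derived, because the effective number of tests
#: behind a published cutoff is often not recoverable from the matrix shape.
DEFAULT_THRESHOLD = 5.49e-10

#: Cap for z-scores derived from underflowed p-values (p reported as 0).
DEFAULT_Z_CAP = 40.0


class MatrixFormatError(ValueError):
    """Raised when an input matrix violates the expected layout."""


def _check_unique(ids: list[str], axis: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixFormatError(f"duplicate {axis} identifier: {x!r}")
        seen.add(x)


@dataclass
class AssociationMatrix:
    """Labeled n_traits × n_genes matrix of association p-values.

    Missing values are stored as NaN and are never treated as significant.
    """

    trait_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.trait_ids) != n or len(self.gene_ids) != m:
            raise MatrixFormatError(
                f"label/shape mismatch: {len(self.trait_ids)} traits, "
                f"{len(self.gene_ids)} genes vs values {self.values.shape}"
            )
        _check_unique(self.trait_ids, "trait")
        _check_unique(self.gene_ids, "gene")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise MatrixFormatError("p-values must lie in [0, 1]")

    @property
    def n_traits(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.trait_ids), columns=list(self.gene_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssociationMatrix":
        return cls(
            trait_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column trait id, header row gene ids."""
        df = self.to_frame()
        df.index.name = "trait"
        # repr-format floats so a round-trip is value-exact
        df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path, sep: str = "\t") -> AssociationMatrix:
    """Read a delimited p-value matrix (header of gene ids, one row per trait).

    Empty cells parse as missing (NaN), never as 0.  Duplicate identifiers
    on either axis and non-numeric cells are errors.  Gzip input is handled
    transparently by extension.
    """
    try:
        # raw header first: pandas silently renames duplicate columns
        header = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str)
        gene_ids = [str(c) for c in header.iloc[0, 1:]]
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"malformed matrix file {path}: {exc}") from exc
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise MatrixFormatError(f"duplicate gene identifier: {g!r}")
        seen.add(g)
    dup_rows = df.index[df.index.duplicated()].tolist()
    if dup_rows:
        raise MatrixFormatError(f"duplicate trait identifier: {dup_rows[0]!r}")
    try:
        values = df.to_numpy(dtype=object)
        values = np.where(
            (values == "") | pd.isna(values), np.nan, values
        ).astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    return AssociationMatrix(
        trait_ids=[str(i) for i in df.index],
        gene_ids=gene_ids,
        values=values,
    )


@dataclass
class BinaryMatrix:
    """Bit-packed binarized association matrix.

    ``packed`` has shape (n_traits, ceil(n_genes / 8)), dtype uint8; gene
    column ``j`` lives in byte ``j // 8`` at bit position ``j % 8``
    (little-endian within a byte).  Bits beyond ``n_genes`` are zero.
    """

    trait_ids: list[str]
    gene_ids: list[str]
    packed: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.packed = np.ascontiguousarray(self.packed, dtype=np.uint8)
        n, nbytes = self.packed.shape
        if len(self.trait_ids) != n:
            raise MatrixFormatError("trait label count does not match rows")
        if nbytes != (len(self.gene_ids) + 7) // 8:
            raise MatrixFormatError("packed width does not match gene count")

    @property
    def n_traits(self) -> int:
        return self.packed.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_dense(
        cls,
        bits: np.ndarray,
        trait_ids: list[str],
        gene_ids: list[str],
        threshold_used: float,
    ) -> "BinaryMatrix":
        bits = np.asarray(bits, dtype=bool)
        packed = np.packbits(bits, axis=1, bitorder="little")
        return cls(trait_ids, gene_ids, packed, threshold_used)

    def to_dense(self) -> np.ndarray:
        return np.unpackbits(self.packed, axis=1, bitorder="little")[
            :, : self.n_genes
        ].astype(bool)

    def row_popcounts(self) -> np.ndarray:
        return np.bitwise_count(self.packed).sum(axis=1, dtype=np.int64)

    def count_ones(self) -> int:
        return int(self.row_popcounts().sum())

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.n_traits}x{self.n_genes}".encode())
        h.update(self.packed.tobytes())
        return h.hexdigest()

    def labels_digest(self) -> str:
        h = hashlib.sha256()
        for t in self.trait_ids:
            h.update(t.encode())
            h.update(b"\x00")
        h.update(b"\x01")
        for g in self.gene_ids:
            h.update(g.encode())
            h.update(b"\x00")
        return h.hexdigest()

    def write_tsv(self, path: str | Path) -> None:
        """Debug view: full 0/1 matrix as TSV."""
        df = pd.DataFrame(
            self.to_dense().astype(int),
            index=list(self.trait_ids),
            columns=list(self.gene_ids),
        )
        df.index.name = "trait"
        df.to_csv(path, sep="\t")

    def write_bitset(self, prefix: str | Path) -> None:
        """Compact dump: one hex row per trait plus a JSON sidecar."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".rows.txt"), "w") as fh:
            for row in self.packed:
                fh.write(row.tobytes().hex())
                fh.write("\n")
        sidecar = {
            "n_traits": self.n_traits,
            "n_genes": self.n_genes,
            "threshold_used": self.threshold_used,
            "labels_digest": self.labels_digest(),
            "trait_ids": list(self.trait_ids),
            "gene_ids": list(self.gene_ids),
            "bit_order": "little-endian within byte, 8 columns per byte",
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
            fh.write("\n")

    @classmethod
    def read_bitset(cls, prefix: str | Path) -> "BinaryMatrix":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        rows = []
        with open(prefix.with_suffix(".rows.txt")) as fh:
            for line in fh:
                rows.append(np.frombuffer(bytes.fromhex(line.strip()), dtype=np.uint8))
        packed = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
        return cls(
            trait_ids=sidecar["trait_ids"],
            gene_ids=sidecar["gene_ids"],
            packed=packed,
            threshold_used=sidecar["threshold_used"],
        )


def binarize(matrix: AssociationMatrix, t: float = DEFAULT_THRESHOLD) -> BinaryMatrix:
    """Threshold the p-value matrix: bit set iff p < t (strictly).

    Missing p-values binarize to 0 — absence of evidence cannot create a
    significant cell.  ``t`` must lie strictly inside (0, 1).
    """
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    with np.errstate(invalid="ignore"):
        bits = matrix.values < t  # NaN < t is False
    return BinaryMatrix.from_dense(bits, matrix.trait_ids, matrix.gene_ids, t)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise cutoff alpha / n_tests for ``n_tests`` >= 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def p_to_z(p, cap: float = DEFAULT_Z_CAP):
    """Absolute two-sided normal quantile of a p-value.

    ``z = Phi^-1(1 - p/2)``; p = 1 maps to 0.  Non-positive p (underflow)
    maps to ``cap`` with a warning, since phenome-scale TWAS matrices
    routinely contain p-values below float precision.  Accepts scalars or
    arrays and returns the matching shape.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr > 1.0):
        raise ValueError("p-values above 1 are invalid")
    under = arr <= 0.0
    if np.any(under):
        warnings.warn(
            f"{int(under.sum())} underflowed p-value(s) capped at z = {cap}",
            stacklevel=2,
        )
    safe = np.where(under, 0.5, arr)
    z = stats.norm.isf(safe / 2.0)
    z = np.where(under, cap, z)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(z)
    return z
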