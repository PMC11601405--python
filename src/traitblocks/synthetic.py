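"""Planted-bicluster synthetic datasets.

Emulates the binarizable structure of a phenome-wide TWAS p-value matrix:
an approximately Uniform(0, 1) background with embedded rectangular blocks
of strongly significant p-values (the planted biclusters) plus sparse,
independent per-cell significance noise.  Annotation collections (GMT-style
term sets) can be generated aligned to the planted blocks, so every
downstream stage — binarization, BiBit, meta-clustering, enrichment — has
known ground truth.

Generation is a pure function of (parameters, seed); the matrix stream and
the annotation stream are independent sub-streams spawned deterministically
from the single dataset seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import GeneSetCollection
from .matrix import AssociationMatrix


def trait_label(i: int) -> str:
    return f"trait_{i:04d}"


def gene_label(j: int) -> str:
    return f"gene_{j:05d}"


@dataclass(frozen=True)
class PlantedBlock:
    """Ground-truth bicluster: a rectangle of significant cells."""

    trait_indices: tuple[int, ...]
    gene_indices: tuple[int, ...]

    def __post_init__(self):
        if not self.trait_indices or not self.gene_indices:
            raise ValueError("planted block must have traits and genes")
        if min(self.trait_indices) < 0 or min(self.gene_indices) < 0:
            raise ValueError("negative index in planted block")

    @property
    def n_cells(self) -> int:
        return len(self.trait_indices) * len(self.gene_indices)


@dataclass(frozen=True)
class BlockSpec:
    """Shape of one block to plant: rows × cols, optionally sharing
    ``overlap_genes`` gene columns with the previously planted block."""

    n_traits: int
    n_genes: int
    overlap_genes: int = 0


def _coerce_spec(spec) -> BlockSpec:
    if isinstance(spec, BlockSpec):
        return spec
    return BlockSpec(*spec)


@dataclass
class SyntheticDataset:
    pvalues: AssociationMatrix
    truth: list[PlantedBlock]
    gene_annotations: GeneSetCollection
    trait_annotations: GeneSetCollection
    seed: int
    params: dict

    def truth_mask(self) -> np.ndarray:
        """Boolean matrix marking cells inside any planted block."""
        mask = np.zeros(
            (self.pvalues.n_traits, self.pvalues.n_genes), dtype=bool
        )
        for block in self.truth:
            mask[np.ix_(block.trait_indices, block.gene_indices)] = True
        return mask

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write matrix TSV, truth JSON and both GMT files; return paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": out_dir / "matrix.tsv",
            "truth": out_dir / "truth.json",
            "gene_annotations": out_dir / "gene_annotations.gmt",
            "trait_annotations": out_dir / "trait_annotations.gmt",
        }
        self.pvalues.write_tsv(paths["matrix"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "params": self.params,
                    "blocks": [
                        {
                            "trait_indices": list(b.trait_indices),
                            "gene_indices": list(b.gene_indices),
                            "trait_ids": [
                                self.pvalues.trait_ids[i] for i in b.trait_indices
                            ],
                            "gene_ids": [
                                self.pvalues.gene_ids[j] for j in b.gene_indices
                            ],
                        }
                        for b in self.truth
                    ],
                },
                fh,
                indent=1,
            )
            fh.write("\n")
        self.gene_annotations.write_gmt(paths["gene_annotations"])
        self.trait_annotations.write_gmt(paths["trait_annotations"])
        return paths


def _place_blocks(
    n_traits: int, n_genes: int, specs: list[BlockSpec]
) -> list[PlantedBlock]:
    """Lay blocks out left-to-right / top-to-bottom, honouring gene overlap
    with the previous block; raise if they run off the matrix."""
    blocks: list[PlantedBlock] = []
    next_trait = 0
    next_gene = 0
    for idx, spec in enumerate(specs):
        if spec.n_traits <= 0 or spec.n_genes <= 0:
            raise ValueError(f"block {idx}: non-positive shape {spec}")
        if spec.overlap_genes < 0 or (
            blocks
            and spec.overlap_genes
            > min(spec.n_genes, len(blocks[-1].gene_indices))
        ):
            raise ValueError(f"block {idx}: invalid gene overlap {spec.overlap_genes}")
        gene_start = next_gene - (spec.overlap_genes if blocks else 0)
        if gene_start < 0:
            raise ValueError(f"block {idx}: overlap exceeds previous block span")
        trait_rng = range(next_trait, next_trait + spec.n_traits)
        gene_rng = range(gene_start, gene_start + spec.n_genes)
        if trait_rng.stop > n_traits or gene_rng.stop > n_genes:
            raise ValueError(
                f"block {idx} ({spec.n_traits}x{spec.n_genes}) exceeds "
                f"matrix dimensions {n_traits}x{n_genes}"
            )
        blocks.append(PlantedBlock(tuple(trait_rng), tuple(gene_rng)))
        next_trait = trait_rng.stop
        next_gene = gene_rng.stop
    return blocks


def generate_planted_dataset(
    n_traits: int,
    n_genes: int,
    blocks,
    signal_p_max: float = 1e-12,
    background_sig_rate: float = 0.01,
    seed: int = 0,
    n_noise_terms: int = 50,
    term_size: int = 15,
) -> SyntheticDataset:
    """Generate a p-value matrix with planted all-significant blocks.

    Background cells are Uniform(0, 1); an independent Bernoulli
    (``background_sig_rate``) subset of them is redrawn Uniform(0,
    ``signal_p_max``) to mimic isolated significant associations.  Cells
    inside planted blocks are Uniform(0, ``signal_p_max``).  Gene- and
    trait-axis annotation collections contain one truth term per block
    plus ``n_noise_terms`` random terms of ``term_size`` members each.

    ``blocks`` is a list of ``BlockSpec`` or ``(rows, cols[, overlap])``
    tuples; overlap is the number of gene columns shared with the previous
    block.
    """
    if n_traits <= 0 or n_genes <= 0:
        raise ValueError("matrix dimensions must be positive")
    if not (0.0 < signal_p_max < 1.0):
        raise ValueError("signal_p_max must be in (0, 1)")
    if not (0.0 <= background_sig_rate < 1.0):
        raise ValueError("background_sig_rate must be in [0, 1)")

    specs = [_coerce_spec(s) for s in blocks]
    placed = _place_blocks(n_traits, n_genes, specs)

    ss = np.random.SeedSequence(seed)
    matrix_rng, gene_ann_rng, trait_ann_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    values = matrix_rng.uniform(0.0, 1.0, size=(n_traits, n_genes))
    if background_sig_rate > 0.0:
        noise = matrix_rng.random(size=(n_traits, n_genes)) < background_sig_rate
        values[noise] = matrix_rng.uniform(0.0, signal_p_max, size=int(noise.sum()))
    for block in placed:
        sub = matrix_rng.uniform(
            0.0, signal_p_max, size=(len(block.trait_indices), len(block.gene_indices))
        )
        values[np.ix_(block.trait_indices, block.gene_indices)] = sub

    pvalues = AssociationMatrix(
        trait_ids=[trait_label(i) for i in range(n_traits)],
        gene_ids=[gene_label(j) for j in range(n_genes)],
        values=values,
    )
    params = {
        "n_traits": n_traits,
        "n_genes": n_genes,
        "blocks": [
            {"n_traits": s.n_traits, "n_genes": s.n_genes, "overlap_genes": s.overlap_genes}
            for s in specs
        ],
        "signal_p_max": signal_p_max,
        "background_sig_rate": background_sig_rate,
        "n_noise_terms": n_noise_terms,
        "term_size": term_size,
    }
    gene_ann = generate_annotations(
        placed,
        axis="gene",
        n_noise_terms=n_noise_terms,
        term_size=min(term_size, n_genes),
        universe_size=n_genes,
        rng=gene_ann_rng,
    )
    trait_ann = generate_annotations(
        placed,
        axis="trait",
        n_noise_terms=n_noise_terms,
        term_size=min(term_size, n_traits),
        universe_size=n_traits,
        rng=trait_ann_rng,
    )
    return SyntheticDataset(
        pvalues=pvalues,
        truth=placed,
        gene_annotations=gene_ann,
        trait_annotations=trait_ann,
        seed=seed,
        params=params,
    )


def generate_annotations(
    blocks: list[PlantedBlock],
    axis: str,
    n_noise_terms: int,
    term_size: int,
    universe_size: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Annotation collection aligned to planted blocks.

    One term per block whose members are exactly that block's indices on
    the chosen axis (term ids ``TRUTH_<axis>_<k>``), plus ``n_noise_terms``
    terms of ``term_size`` members drawn uniformly without replacement
    from the universe (ids ``NOISE_<axis>_<k>``).  Pass either ``seed`` or
    an already-constructed ``rng``.
    """
    if axis not in ("gene", "trait"):
        raise ValueError("axis must be 'gene' or 'trait'")
    if term_size > universe_size:
        raise ValueError("term_size cannot exceed universe_size")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed or 0))
    label = gene_label if axis == "gene" else trait_label

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for k, block in enumerate(blocks):
        idx = block.gene_indices if axis == "gene" else block.trait_indices
        terms[f"TRUTH_{axis}_{k}"] = (
            f"planted block {k} ({axis} axis)",
            frozenset(label(i) for i in idx),
        )
    for k in range(n_noise_terms):
        members = rng.choice(universe_size, size=term_size, replace=False)
        terms[f"NOISE_{axis}_{k:04d}"] = (
            f"random {axis} set {k}",
            frozenset(label(int(i)) for i in members),
        )
    if not terms:
        warnings.warn("empty annotation collection generated", stacklevel=2)
    return GeneSetCollection(terms=terms, axis=axis)
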