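"""End-to-end orchestration: binarize → BiBit → filter → cluster → enrich.

A single :class:`PipelineConfig` drives the run; every stage parameter is
recorded in a run manifest together with input and output digests, so a
run can be reproduced and verified byte-for-byte.  All randomness lives in
the synthetic-data generator: the analysis path itself is deterministic,
and the seed is recorded but only consumed when the config simulates its
input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bibit import run_bibit
from .enrichment import enrich_meta, read_gmt, write_enrichment_tsv
from .matrix import DEFAULT_THRESHOLD, binarize, read_matrix
from .metacluster import (
    average_linkage_cluster,
    filter_biclusters,
    pairwise_similarity,
    summarize_meta,
    write_labels_tsv,
    write_meta_summary_tsv,
)
from .synthetic import generate_planted_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class SimulateBlock:
    """Generator parameters for a simulated input (see synthetic module)."""

    n_traits: int
    n_genes: int
    blocks: list  # list of [rows, cols] or [rows, cols, overlap]
    signal_p_max: float = 1e-12
    background_sig_rate: float = 0.01
    n_noise_terms: int = 50
    term_size: int = 15


@dataclass
class PipelineConfig:
    """Everything one run needs; no implicit defaults survive to the manifest."""

    out_dir: str
    matrix_path: str | None = None
    simulate: SimulateBlock | None = None
    threshold: float = DEFAULT_THRESHOLD
    mnr: int = 2
    mnc: int = 2
    min_genes: int = 10
    required_trait_ids: list[str] = field(default_factory=list)
    trait_pattern: str | None = None
    k: int = 10
    gene_sets_path: str | None = None  # None with simulate => generated GMTs
    trait_sets_path: str | None = None
    gene_universe: str = "matrix"  # "matrix" or a one-id-per-line file
    trait_universe: str = "matrix"
    seed: int = 0

    def validate(self) -> None:
        if (self.matrix_path is None) == (self.simulate is None):
            raise ValueError("exactly one of matrix_path or simulate must be set")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config mirroring the PipelineConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(
        **{k: v for k, v in raw.items()},
        simulate=SimulateBlock(**sim) if sim else None,
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _line_count(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


@dataclass
class RunManifest:
    """Snapshot sufficient to re-execute and verify a run."""

    config: dict
    version: str
    started: str
    finished: str
    input_digests: dict
    stage_outputs: dict  # stage -> {file: {sha256, lines}}
    counts: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def config_from_manifest(manifest: RunManifest, out_dir: str) -> PipelineConfig:
    """Rebuild a runnable config from a manifest's recorded snapshot."""
    raw = dict(manifest.config)
    raw["out_dir"] = out_dir
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw, simulate=SimulateBlock(**sim) if sim else None)
    cfg.validate()
    return cfg


def _read_universe(spec: str, matrix_ids: list[str]) -> frozenset[str]:
    if spec == "matrix":
        return frozenset(matrix_ids)
    with open(spec) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, writing outputs and a manifest under out_dir.

    Any stage error aborts with :class:`PipelineError` naming the stage;
    outputs of completed stages are retained and a FAILED marker is
    written.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stage_outputs: dict[str, dict] = {}
    counts: dict[str, int] = {}
    input_digests: dict[str, str] = {}
    stage = "setup"

    def record(stage_name: str, *paths: Path) -> None:
        stage_outputs[stage_name] = {
            p.name: {"sha256": _sha256(p), "lines": _line_count(p)} for p in paths
        }

    try:
        # --- input ----------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            dataset = generate_planted_dataset(
                n_traits=sim.n_traits,
                n_genes=sim.n_genes,
                blocks=[tuple(b) for b in sim.blocks],
                signal_p_max=sim.signal_p_max,
                background_sig_rate=sim.background_sig_rate,
                seed=config.seed,
                n_noise_terms=sim.n_noise_terms,
                term_size=sim.term_size,
            )
            paths = dataset.write(out_dir)
            record("simulate", *paths.values())
            matrix = dataset.pvalues
            gene_sets = dataset.gene_annotations
            trait_sets = dataset.trait_annotations
            input_digests["matrix"] = _sha256(paths["matrix"])
        else:
            stage = "read_matrix"
            matrix = read_matrix(config.matrix_path)
            input_digests["matrix"] = _sha256(Path(config.matrix_path))
            gene_sets = trait_sets = None

        if config.gene_sets_path:
            stage = "read_annotations"
            gene_sets = read_gmt(config.gene_sets_path, axis="gene")
            input_digests["gene_sets"] = _sha256(Path(config.gene_sets_path))
        if config.trait_sets_path:
            stage = "read_annotations"
            trait_sets = read_gmt(config.trait_sets_path, axis="trait")
            input_digests["trait_sets"] = _sha256(Path(config.trait_sets_path))
        if gene_sets is None or trait_sets is None:
            raise ValueError(
                "annotation collections required: provide GMT paths or simulate"
            )

        # --- binarize ---------------------------------------------------
        stage = "binarize"
        binary = binarize(matrix, config.threshold)
        binary.write_bitset(out_dir / "binarized")
        counts["ones"] = binary.count_ones()
        record(
            "binarize",
            out_dir / "binarized.rows.txt",
            out_dir / "binarized.json",
        )

        # --- bibit ------------------------------------------------------
        stage = "bibit"
        bset = run_bibit(binary, mnr=config.mnr, mnc=config.mnc)
        bset.write_jsonl(out_dir / "biclusters.jsonl")
        bset.write_summary_tsv(out_dir / "biclusters_summary.tsv")
        counts["biclusters"] = len(bset)
        record(
            "bibit",
            out_dir / "biclusters.jsonl",
            out_dir / "biclusters_summary.tsv",
        )

        # --- filter -----------------------------------------------------
        stage = "filter"
        filtered = filter_biclusters(
            bset,
            min_genes=config.min_genes,
            required_trait_ids=config.required_trait_ids,
            trait_pattern=config.trait_pattern,
        )
        filtered.write_jsonl(out_dir / "filtered_biclusters.jsonl")
        counts["filtered_biclusters"] = len(filtered)
        record("filter", out_dir / "filtered_biclusters.jsonl")
        if len(filtered) < 2:
            raise ValueError(
                f"only {len(filtered)} bicluster(s) pass the filter; "
                "need at least 2 to cluster"
            )

        # --- metacluster --------------------------------------------------
        stage = "metacluster"
        sim_matrix = pairwise_similarity(filtered)
        sim_matrix.write_tsv(out_dir / "similarity.tsv")
        k = min(config.k, len(filtered))
        labels = average_linkage_cluster(sim_matrix, k)
        metas = summarize_meta(filtered, labels)
        write_labels_tsv(filtered, labels, out_dir / "meta_labels.tsv")
        write_meta_summary_tsv(metas, out_dir / "meta_summary.tsv")
        counts["meta_biclusters"] = len(metas)
        record(
            "metacluster",
            out_dir / "similarity.tsv",
            out_dir / "meta_labels.tsv",
            out_dir / "meta_summary.tsv",
        )

        # --- enrichment ---------------------------------------------------
        stage = "enrich"
        gene_universe = _read_universe(config.gene_universe, matrix.gene_ids)
        trait_universe = _read_universe(config.trait_universe, matrix.trait_ids)
        tables = enrich_meta(metas, gene_sets, trait_sets, gene_universe, trait_universe)
        write_enrichment_tsv(tables, "gene", out_dir / "enrichment_genes.tsv")
        write_enrichment_tsv(tables, "trait", out_dir / "enrichment_traits.tsv")
        counts["enrichment_rows_gene"] = sum(len(t["gene"]) for t in tables.values())
        counts["enrichment_rows_trait"] = sum(len(t["trait"]) for t in tables.values())
        record(
            "enrich",
            out_dir / "enrichment_genes.tsv",
            out_dir / "enrichment_traits.tsv",
        )
    except Exception as exc:
        marker = out_dir / "FAILED"
        marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        input_digests=input_digests,
        stage_outputs=stage_outputs,
        counts=counts,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
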