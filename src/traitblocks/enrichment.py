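"""Hypergeometric over-representation analysis (ORA) of identifier sets.

A meta-bicluster's gene union is tested against gene-set collections
(GO-style GMT files) and its trait set against trait-set collections
(DO-style GMT files).  For a universe of N identifiers, a term with K
members in the universe, and a query of n identifiers of which k fall in
the term, the p-value is the upper-tail hypergeometric probability
P(X >= k) — the standard ORA convention of including the observed overlap.
P-values are Benjamini-Hochberg adjusted across the terms of one
collection for one query.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class GMTFormatError(ValueError):
    """Raised for malformed GMT input."""


@dataclass
class GeneSetCollection:
    """Flat collection of annotation terms on one axis.

    ``terms`` maps a term id to ``(name, member identifier set)``.
    ``axis`` records whether members are gene or trait identifiers.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    axis: str = "gene"

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise GMTFormatError(f"term {term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term_id, (name, members) in self.terms.items():
                fh.write("\t".join([term_id, name, *sorted(members)]))
                fh.write("\n")


def read_gmt(path: str | Path, axis: str = "gene") -> GeneSetCollection:
    """Parse a GMT file: term id, description, then tab-separated members.

    Duplicate members within a term are collapsed; a duplicated term id
    across lines is an error; an empty file yields an empty collection
    with a warning.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term_id, name, *members = fields
            if term_id in terms:
                raise GMTFormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (name, frozenset(m for m in members if m))
    if not terms:
        warnings.warn(f"GMT file {path} contains no terms", stacklevel=2)
    return GeneSetCollection(terms=terms, axis=axis)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overlap counts and significance for one query."""

    term_id: str
    term_name: str
    overlap_k: int
    term_size_K: int
    query_size_n: int
    universe_size_N: int
    p_value: float
    adjusted_p: float
    overlap_members: tuple[str, ...]


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of a query against each term.

    Query members outside the universe are dropped (count logged); each
    term is intersected with the universe before testing, and terms that
    become empty carry no test and are omitted.  Results are BH-adjusted
    across the tested terms and sorted by (p-value, term id).
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = frozenset(query)
    dropped = len(query_set - universe_set)
    if dropped:
        log.info("dropped %d query members outside the universe", dropped)
    query_set &= universe_set
    if not query_set:
        raise ValueError("query is empty after intersection with the universe")

    N = len(universe_set)
    n = len(query_set)
    rows: list[tuple[str, str, int, int, tuple[str, ...], float]] = []
    for term_id, (name, members) in collection.terms.items():
        in_universe = members & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        overlap = tuple(sorted(query_set & in_universe))
        k = len(overlap)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, name, k, K, overlap, min(p, 1.0)))

    if not rows:
        return []
    _, _, _, _, _, pvals = zip(*rows)
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=name,
            overlap_k=k,
            term_size_K=K,
            query_size_n=n,
            universe_size_N=N,
            p_value=p,
            adjusted_p=float(max(adj, p)),
            overlap_members=overlap,
        )
        for (term_id, name, k, K, overlap, p), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrich_meta(
    metas,
    gene_sets: GeneSetCollection,
    trait_sets: GeneSetCollection,
    gene_universe: Iterable[str],
    trait_universe: Iterable[str],
) -> dict[str, dict[str, list[EnrichmentResult]]]:
    """ORA per meta-bicluster on both axes.

    The gene-axis query is the meta's gene union; the trait-axis query is
    the set of traits appearing in any member bicluster.  Returns
    ``{meta label: {"gene": [...], "trait": [...]}}``.
    """
    gene_universe = frozenset(gene_universe)
    trait_universe = frozenset(trait_universe)
    tables: dict[str, dict[str, list[EnrichmentResult]]] = {}
    for meta in metas:
        tables[meta.label] = {
            "gene": ora(meta.gene_union, gene_sets, gene_universe),
            "trait": ora(meta.trait_union, trait_sets, trait_universe),
        }
    return tables


def write_enrichment_tsv(
    tables: Mapping[str, Mapping[str, list[EnrichmentResult]]],
    axis: str,
    path: str | Path,
) -> None:
    """Write one axis of an ``enrich_meta`` result as a flat TSV."""
    header = [
        "meta_label",
        "term_id",
        "name",
        "k",
        "K",
        "n",
        "N",
        "p_value",
        "adjusted_p",
        "overlap_members",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for label in tables:
            for r in tables[label][axis]:
                fh.write(
                    "\t".join(
                        [
                            label,
                            r.term_id,
                            r.term_name,
                            str(r.overlap_k),
                            str(r.term_size_K),
                            str(r.query_size_n),
                            str(r.universe_size_N),
                            f"{r.p_value:.6e}",
                            f"{r.adjusted_p:.6e}",
                            ",".join(r.overlap_members),
                        ]
                    )
                    + "\n"
                )
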