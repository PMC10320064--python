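"""Process catalogs: named gene sets and their gene membership.

A *process* is a named set of genes — a GO biological-process term from a
BioMart-style two-column dump, or an MSigDB-style gene set from a GMT file.
Catalogs are flat: annotations are used exactly as listed, with no ontology
propagation.
"""

from __future__ import annotations

import gzip
import re
from collections.abc import Iterable, Iterator, Mapping, Set
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = [
    "ProcessTerm",
    "ProcessCatalog",
    "load_catalog",
    "filter_catalog",
    "processes_of_gene",
    "write_catalog_tsv",
]

_GO_ID = re.compile(r"GO:\d+")
# Tokens that mark a two-column first line as a header rather than data.
_HEADER_TOKENS = {
    "gene", "genes", "gene_name", "gene_symbol", "symbol", "gene stable id",
    "process", "process_id", "process_name", "go_id", "go id", "term",
    "go term accession", "go term name", "name",
}


@dataclass(frozen=True)
class ProcessTerm:
    """One process: an identifier, a human-readable name, and its gene set.

    ``n_expressed`` is populated by :func:`filter_catalog` and records how many
    of the term's genes were found in the expressed-gene universe; the full
    annotated gene set is always retained.
    """

    process_id: str
    name: str
    genes: frozenset[str]
    n_expressed: int | None = None

    def __post_init__(self) -> None:
        if not self.process_id:
            raise ValueError("process_id must be non-empty")
        if not isinstance(self.genes, frozenset):
            object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"term {self.process_id!r} has an empty gene set")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


class ProcessCatalog:
    """An ordered collection of :class:`ProcessTerm` with a gene reverse index."""

    def __init__(self, terms: Iterable[ProcessTerm], source: str = "") -> None:
        self._terms: dict[str, ProcessTerm] = {}
        for term in terms:
            if term.process_id in self._terms:
                raise ValueError(f"duplicate process_id {term.process_id!r}")
            self._terms[term.process_id] = term
        self.source = source
        self._gene_index: dict[str, frozenset[str]] | None = None

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[ProcessTerm]:
        return iter(self._terms.values())

    def __contains__(self, process_id: object) -> bool:
        return process_id in self._terms

    def __getitem__(self, process_id: str) -> ProcessTerm:
        return self._terms[process_id]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProcessCatalog({len(self)} terms, source={self.source!r})"

    @property
    def terms(self) -> list[ProcessTerm]:
        return list(self._terms.values())

    @property
    def process_ids(self) -> list[str]:
        return list(self._terms)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_index)

    @property
    def gene_index(self) -> Mapping[str, frozenset[str]]:
        """Reverse map gene -> ids of the terms annotating it (built lazily)."""
        if self._gene_index is None:
            idx: dict[str, set[str]] = {}
            for term in self:
                for g in term.genes:
                    idx.setdefault(g, set()).add(term.process_id)
            self._gene_index = {g: frozenset(s) for g, s in idx.items()}
        return self._gene_index

    def processes_of_gene(self, gene: str) -> list[ProcessTerm]:
        """All terms whose gene set contains ``gene``, sorted by process_id."""
        ids = self.gene_index.get(gene, frozenset())
        return [self._terms[pid] for pid in sorted(ids)]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) >= 2 and _GO_ID.fullmatch(fields[1].strip()):
        return False
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def _parse_tsv2col(lines: Iterable[str]) -> list[ProcessTerm]:
    # (gene, process_id[, process_name]) rows; duplicates collapse.
    genes_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    first_data_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if not first_data_seen and _looks_like_header(fields):
            first_data_seen = True
            continue
        first_data_seen = True
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(
                f"malformed two-column TSV at line {lineno}: "
                f"expected at least (gene, process_id), got {line!r}"
            )
        gene, pid = fields[0].strip(), fields[1].strip()
        genes_by_term.setdefault(pid, set()).add(gene)
        if len(fields) >= 3 and fields[2].strip() and pid not in names:
            names[pid] = fields[2].strip()
    return [
        ProcessTerm(pid, names.get(pid, pid), frozenset(gs))
        for pid, gs in genes_by_term.items()
    ]


def _parse_gmt(lines: Iterable[str]) -> list[ProcessTerm]:
    terms: list[ProcessTerm] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"malformed GMT at line {lineno}: expected "
                f"(name, description, gene, ...), got {len(fields)} fields"
            )
        name = fields[0].strip()
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        if not name or not genes:
            raise ValueError(f"malformed GMT at line {lineno}: empty set name or gene list")
        terms.append(ProcessTerm(name, fields[1].strip() or name, genes))
    return terms


def load_catalog(path: str | Path, format: str = "tsv2col") -> ProcessCatalog:
    """Read a process catalog from disk.

    Parameters
    ----------
    path
        Two-column TSV (``gene<TAB>process_id[<TAB>process_name]``, optionally
        gzipped) or a GMT file (``set_name<TAB>description<TAB>gene...``).
    format
        ``"tsv2col"`` or ``"gmt"``.
    """
    if format not in ("tsv2col", "gmt"):
        raise ValueError(f"unknown catalog format {format!r}")
    with _open_text(path) as fh:
        terms = _parse_tsv2col(fh) if format == "tsv2col" else _parse_gmt(fh)
    if not terms:
        raise ValueError(f"no terms parsed from {path}")
    return ProcessCatalog(terms, source=str(path))


def filter_catalog(
    catalog: ProcessCatalog,
    expressed_genes: Set[str],
    min_genes: int = 3,
    max_genes: int = 100,
    *,
    case_insensitive: bool = False,
) -> ProcessCatalog:
    """Keep terms whose *expressed* gene count lies in ``[min_genes, max_genes]``.

    The band is closed at both ends; the default 3–100 is the usual working
    range for process scoring (very small sets are unstable, very large ones
    uninformative). Retained terms keep their full annotated gene set and carry
    ``n_expressed``.
    """
    if not expressed_genes:
        raise ValueError("expressed_genes is empty; nothing can be scored")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if min_genes > max_genes:
        raise ValueError("min_genes must be <= max_genes")
    if case_insensitive:
        universe = {g.upper() for g in expressed_genes}

        def n_expr(t: ProcessTerm) -> int:
            return sum(1 for g in t.genes if g.upper() in universe)
    else:
        universe = set(expressed_genes)

        def n_expr(t: ProcessTerm) -> int:
            return len(t.genes & universe)

    kept = []
    for term in catalog:
        n = n_expr(term)
        if min_genes <= n <= max_genes:
            kept.append(replace(term, n_expressed=n))
    return ProcessCatalog(kept, source=f"{catalog.source}|filtered[{min_genes},{max_genes}]")


def processes_of_gene(catalog: ProcessCatalog, gene: str) -> list[ProcessTerm]:
    """All catalog terms containing ``gene`` (sorted by id; empty if unknown)."""
    return catalog.processes_of_gene(gene)


def write_catalog_tsv(catalog: ProcessCatalog, path: str | Path) -> None:
    """Write a catalog as a two-column TSV (gene, process_id, process_name)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tprocess_id\tprocess_name\n")
        for term in catalog:
            for gene in sorted(term.genes):
                fh.write(f"{gene}\t{term.process_id}\t{term.name}\n")
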