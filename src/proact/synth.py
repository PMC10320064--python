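"""Synthetic fixtures with planted structure for every pipeline stage.

The generator emulates the method's input layer, not raw sequencing reads: a
Gaussian log2 fold-change background, process terms drawn from a gene pool,
planted (term, context) effects as mean shifts, and optional outlier
replacement to exercise the trimmed mean. Cell-type benchmarks assign each
context a true identity whose group terms are planted with a positive effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ProcessCatalog, ProcessTerm
from .celltypes import CellTypeGroups
from .demat import DEMatrix

__all__ = [
    "PlantSpec",
    "make_catalog",
    "make_de_matrix",
    "make_groups",
    "make_annotation_benchmark",
]


@dataclass
class PlantSpec:
    """Parameters of one synthetic scenario.

    ``planted`` lists (process_id, context, effect) mean shifts in log2FC
    units. ``noise_sd`` is the background standard deviation on the log2FC
    scale; 0.5 is a realistic between-context spread for most genes.
    ``outlier_rate`` is the per-value probability of replacement by an
    extreme draw at ±10·noise_sd, emulating single dramatically
    differentially expressed genes.
    """

    n_genes: int = 500
    n_contexts: int = 10
    n_terms: int = 20
    term_size_range: tuple[int, int] = (3, 100)
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 0.5
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("max term size exceeds the gene pool")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must lie in [0, 0.5)")
        for _, _, effect in self.planted:
            if not np.isfinite(effect):
                raise ValueError("planted effects must be finite")

    # deterministic child streams so, e.g., outliers toggle without
    # perturbing the background draws
    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def context_ids(self) -> list[str]:
        return [f"C{i:02d}" for i in range(1, self.n_contexts + 1)]

    @property
    def term_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_terms + 1)]


def make_catalog(spec: PlantSpec, *, disjoint: bool = False) -> ProcessCatalog:
    """Seeded random catalog: term sizes uniform in range, genes drawn without
    replacement per term.

    With ``disjoint=True`` no gene is shared between terms (required when
    planted effects must not bleed across terms); infeasible pool sizes raise.
    """
    rng = spec.rng(0)
    lo, hi = spec.term_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_terms)
    genes = spec.gene_ids
    terms = []
    if disjoint:
        if int(sizes.sum()) > spec.n_genes:
            raise ValueError(
                f"infeasible spec: disjoint terms need {int(sizes.sum())} genes, "
                f"pool has {spec.n_genes}"
            )
        pool = rng.permutation(genes)
        start = 0
        for tid, size in zip(spec.term_ids, sizes):
            members = pool[start : start + size]
            start += size
            terms.append(ProcessTerm(tid, f"synthetic process {tid}", frozenset(members)))
    else:
        for tid, size in zip(spec.term_ids, sizes):
            members = rng.choice(genes, size=size, replace=False)
            terms.append(ProcessTerm(tid, f"synthetic process {tid}", frozenset(members)))
    return ProcessCatalog(terms, source=f"synthetic(seed={spec.seed})")


def make_de_matrix(spec: PlantSpec, catalog: ProcessCatalog) -> DEMatrix:
    """Gaussian background + planted mean shifts + optional outlier replacement.

    Background values are Normal(0, noise_sd). For each planted
    (term, context, effect), the term's member genes get ``effect`` added in
    that context. Finally each value is independently replaced by
    ±10·noise_sd with probability ``outlier_rate`` (outliers use their own
    random stream, so toggling them leaves the background unchanged).
    """
    for tid, ctx, _ in spec.planted:
        if tid not in catalog:
            raise ValueError(f"planted term {tid!r} not in catalog")
        if ctx not in spec.context_ids:
            raise ValueError(f"planted context {ctx!r} not in spec")
    rng_bg = spec.rng(1)
    values = rng_bg.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_contexts))
    gene_pos = {g: i for i, g in enumerate(spec.gene_ids)}
    ctx_pos = {c: j for j, c in enumerate(spec.context_ids)}
    for tid, ctx, effect in spec.planted:
        rows = [gene_pos[g] for g in sorted(catalog[tid].genes)]
        values[rows, ctx_pos[ctx]] += effect
    if spec.outlier_rate > 0:
        rng_out = spec.rng(2)
        mask = rng_out.random(values.shape) < spec.outlier_rate
        signs = rng_out.choice([-1.0, 1.0], size=values.shape)
        values[mask] = (signs * 10.0 * spec.noise_sd)[mask]
    return DEMatrix(pd.DataFrame(values, index=spec.gene_ids, columns=spec.context_ids))


def make_groups(
    spec: PlantSpec, catalog: ProcessCatalog, n_cell_types: int
) -> tuple[CellTypeGroups, dict[str, str]]:
    """Partition terms into disjoint cell-type groups and assign identities.

    Each of the ``n_cell_types`` groups receives a near-equal share of the
    catalog's terms; each context (cell subset) is assigned a true identity,
    cycling through the cell types. Returns (groups, subset → identity map).
    """
    if n_cell_types < 1:
        raise ValueError("n_cell_types must be >= 1")
    if n_cell_types > spec.n_contexts:
        raise ValueError("infeasible partition: more cell types than contexts")
    if n_cell_types > len(catalog):
        raise ValueError("infeasible partition: more cell types than terms")
    labels = [f"celltype_{i:02d}" for i in range(1, n_cell_types + 1)]
    assignment: dict[str, set[str]] = {lab: set() for lab in labels}
    for i, term in enumerate(catalog):
        assignment[labels[i % n_cell_types]].add(term.process_id)
    identity = {
        ctx: labels[j % n_cell_types] for j, ctx in enumerate(spec.context_ids)
    }
    groups = CellTypeGroups(assignment, source=f"synthetic(seed={spec.seed})")
    return groups, identity


@dataclass
class AnnotationBenchmark:
    """A complete planted cell-type annotation scenario."""

    spec: PlantSpec
    catalog: ProcessCatalog
    dem: DEMatrix
    groups: CellTypeGroups
    identity: dict[str, str]
    truth: pd.DataFrame  # planted (context, cell_type, process_id, effect)


def make_annotation_benchmark(
    spec: PlantSpec, n_cell_types: int, effect: float = 2.0
) -> AnnotationBenchmark:
    """Disjoint catalog + groups + DE matrix where each subset's true identity
    has all its group's terms planted with ``effect``."""
    catalog = make_catalog(spec, disjoint=True)
    groups, identity = make_groups(spec, catalog, n_cell_types)
    planted = [
        (tid, ctx, effect)
        for ctx, label in identity.items()
        for tid in sorted(groups[label])
    ]
    spec.planted = planted
    dem = make_de_matrix(spec, catalog)
    truth = pd.DataFrame(
        [(ctx, identity[ctx], tid, effect) for tid, ctx, effect in planted],
        columns=["context", "cell_type", "process_id", "effect"],
    )
    return AnnotationBenchmark(spec, catalog, dem, groups, identity, truth)
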