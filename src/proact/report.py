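"""Query and visualization layer: process, gene, context and subset queries.

Every query is a pure projection of a :class:`~proact.scoring.ScoreTable`;
nothing is recomputed. Every rendered figure is accompanied by a TSV twin of
the plotted values, which is the machine-checkable surface of the plot.
Heatmap color scales are diverging and anchored at 0, honoring the sign
semantics (positive = preferentially active, negative = downregulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .catalog import ProcessCatalog
from .scoring import ScoreTable

__all__ = [
    "QueryResult",
    "query_process",
    "query_gene",
    "query_context",
    "query_subset",
    "render",
]

_KIND_FOR_MODE = {
    "process": "heatmap",
    "gene": "heatmap",
    "context": "barplot",
    "subset": "dotplot",
}


@dataclass
class QueryResult:
    """A view of ScoreTable content selected by one query.

    ``values`` is a processes × contexts matrix for heatmap modes, or a
    ranked record frame for context/subset modes.
    """

    mode: str
    values: pd.DataFrame
    hints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _KIND_FOR_MODE:
            raise ValueError(f"unknown query mode {self.mode!r}")
        self.hints.setdefault("center", 0.0)


def query_process(table: ScoreTable, process_ids) -> QueryResult:
    """Score matrix of the requested processes (rows, request order) × all contexts."""
    if isinstance(process_ids, str):
        process_ids = [process_ids]
    process_ids = list(process_ids)
    known = set(table.process_ids)
    unknown = [p for p in process_ids if p not in known]
    if unknown:
        raise ValueError(f"unknown process id(s): {', '.join(map(repr, unknown))}")
    matrix = table.matrix().loc[process_ids]
    return QueryResult(mode="process", values=matrix)


def query_gene(table: ScoreTable, catalog: ProcessCatalog, gene: str) -> QueryResult:
    """Score matrix of all scored processes that involve ``gene``."""
    related = [t.process_id for t in catalog.processes_of_gene(gene)]
    scored = set(table.process_ids)
    pids = [p for p in related if p in scored]
    if not pids:
        raise ValueError(f"gene {gene!r} occurs in no scored process")
    matrix = table.matrix().loc[pids]
    return QueryResult(mode="gene", values=matrix, hints={"gene": gene})


def query_context(
    table: ScoreTable, context: str, top_k: int = 5, direction: str = "up"
) -> QueryResult:
    """Top processes in one context, by score.

    ``direction="up"`` returns the most preferentially active, ``"down"`` the
    most downregulated; ties break by process_id.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if context not in set(table.contexts):
        raise ValueError(f"unknown context {context!r}")
    rec = table.records
    sub = rec[(rec["context"] == context) & rec["score"].notna()]
    sub = sub.sort_values(
        ["score", "process_id"], ascending=[direction == "down", True], kind="stable"
    )
    cols = ["process_id", "process_name", "score", "n_genes_used"]
    return QueryResult(
        mode="context",
        values=sub.head(top_k)[cols].reset_index(drop=True),
        hints={"context": context, "direction": direction},
    )


def query_subset(group_records: pd.DataFrame, subset: str, top_k: int = 10) -> QueryResult:
    """Ranked cell-type group scores for one subset (input: group_scores output)."""
    from .celltypes import rank_cell_types

    ranked = rank_cell_types(group_records, subset, top_k=top_k)
    return QueryResult(mode="subset", values=ranked, hints={"subset": subset})


def _tsv_twin_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".tsv")


def render(result: QueryResult, path: str | Path, kind: str | None = None) -> tuple[Path, Path]:
    """Write ``result`` as an image plus a TSV twin of the plotted values.

    Returns (image_path, tsv_path). The kind must match the query mode:
    heatmap for process/gene, barplot for context, dotplot for subset.
    """
    if result.values.empty:
        raise ValueError("cannot render an empty query result")
    expected = _KIND_FOR_MODE[result.mode]
    kind = kind or expected
    if kind != expected:
        raise ValueError(f"kind {kind!r} is not supported for mode {result.mode!r}")
    path = Path(path)
    tsv = _tsv_twin_path(path)
    fig = Figure(figsize=(8, max(2.5, 0.3 * len(result.values) + 1.5)))
    ax = fig.add_subplot(111)
    if kind == "heatmap":
        mat = result.values
        amax = float(np.nanmax(np.abs(mat.to_numpy()))) or 1.0
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-amax, vmax=amax, aspect="auto")
        ax.set_xticks(range(mat.shape[1]), labels=mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(mat.shape[0]), labels=mat.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="preferential activity score")
        mat.to_csv(tsv, sep="\t", index_label="process_id")
    elif kind == "barplot":
        sub = result.values
        colors = np.where(sub["score"] >= 0, "#b2182b", "#2166ac")
        ax.barh(range(len(sub))[::-1], sub["score"], color=colors)
        ax.set_yticks(range(len(sub))[::-1], labels=sub["process_name"], fontsize=7)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("preferential activity score")
        ax.set_title(str(result.hints.get("context", "")))
        sub.to_csv(tsv, sep="\t", index=False)
    else:  # dotplot
        sub = result.values
        ax.scatter(sub["rank"], sub["group_score"], s=30, color="#2166ac")
        for _, r in sub.iterrows():
            ax.annotate(
                r["cell_type"], (r["rank"], r["group_score"]),
                textcoords="offset points", xytext=(4, 3), fontsize=7,
            )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("rank")
        ax.set_ylabel("cell-type group score")
        ax.set_title(str(result.hints.get("subset", "")))
        sub.to_csv(tsv, sep="\t", index=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    return path, tsv
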