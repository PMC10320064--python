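"""Differential-expression matrices: the method's sole quantitative input.

A :class:`DEMatrix` holds log2 fold-change-like values for genes (rows) across
contexts (columns) — tissues, cell clusters, conditions. It can be read from a
wide TSV, pivoted from a long marker table (one row per gene × cluster, as
produced by common single-cell toolkits), or derived from a per-subset
mean-expression table via the preferential-expression transform.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEMatrix",
    "load_wide_tsv",
    "from_marker_table",
    "preferential_expression",
    "validate",
    "write_wide_tsv",
    "write_marker_table",
]


class DEMatrix:
    """Genes × contexts matrix of differential-expression values.

    Missing entries are NaN and are excluded from downstream scoring rather
    than imputed. At least one gene and two contexts are required: differential
    expression is defined relative to other contexts.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        data = data.astype(float)
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate gene row {dup!r}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate context column {dup!r}")
        if data.shape[0] < 1:
            raise ValueError("DEMatrix needs at least 1 gene")
        if data.shape[1] < 2:
            raise ValueError(
                "DEMatrix needs at least 2 contexts (values are relative to other contexts)"
            )
        if np.isinf(data.to_numpy()).any():
            raise ValueError("DEMatrix values must be finite where present")
        self.data = data

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def contexts(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, c = self.shape
        return f"DEMatrix({g} genes x {c} contexts, {self.n_missing} missing)"

    def to_samples_frame(self) -> pd.DataFrame:
        """Transpose to the contexts-as-rows orientation used by estimators."""
        return self.data.T


def load_wide_tsv(path: str | Path) -> DEMatrix:
    """Read a wide genes × contexts TSV (first column gene ids, header contexts).

    Empty cells become missing (NaN). Non-numeric cells and duplicated labels
    are hard errors, reported with the offending gene/context.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    contexts = header[1:]
    seen: set[str] = set()
    for c in contexts:
        if c in seen:
            raise ValueError(f"duplicate context column {c!r} in {path}")
        seen.add(c)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=True)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene row {dup!r} in {path}")
    num = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = num.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"context {raw.columns[j]!r} in {path}"
        )
    num.index.name = None
    num.columns.name = None
    return DEMatrix(num)


def from_marker_table(
    path: str | Path,
    gene_col: str = "gene",
    context_col: str = "cluster",
    value_col: str = "avg_log2FC",
    fill_missing: str = "missing",
    sep: str | None = None,
) -> DEMatrix:
    """Pivot a long marker table (gene, cluster, log2FC) to a wide DEMatrix.

    ``fill_missing`` controls (gene, context) pairs absent from the table:
    ``"missing"`` (default) flags them missing — marker tables usually omit
    non-significant genes and imputing 0 is an opt-in modeling choice —
    while ``"zero"`` fills 0.
    """
    if fill_missing not in ("zero", "missing"):
        raise ValueError(f"fill_missing must be 'zero' or 'missing', got {fill_missing!r}")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (gene_col, context_col, value_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (have {list(df.columns)})")
    dup = df.duplicated(subset=[gene_col, context_col])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicated (gene, context) pair ({row[gene_col]!r}, {row[context_col]!r})"
        )
    values = pd.to_numeric(df[value_col], errors="raise")
    wide = df.assign(**{value_col: values}).pivot(
        index=gene_col, columns=context_col, values=value_col
    )
    wide.index.name = None
    wide.columns.name = None
    if fill_missing == "zero":
        wide = wide.fillna(0.0)
    return DEMatrix(wide)


def preferential_expression(
    mean_expression: pd.DataFrame, pseudocount: float = 1.0
) -> DEMatrix:
    """Per-gene expression of each subset relative to the average of the others.

    value(g, s) = log2( (me(g,s) + pc) / (mean_{s' != s} me(g,s') + pc) )

    The pseudocount guards zero expression; the leave-one-out mean makes the
    value a *preferential* quantity: positive where the gene is higher in the
    subset than elsewhere, zero for a gene expressed identically everywhere.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = mean_expression.astype(float)
    if df.shape[1] < 2:
        raise ValueError("preferential expression needs at least 2 subsets")
    vals = df.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("mean expression values must be finite")
    if (vals < 0).any():
        raise ValueError("mean expression values must be non-negative")
    n = vals.shape[1]
    others = (vals.sum(axis=1, keepdims=True) - vals) / (n - 1)
    out = np.log2((vals + pseudocount) / (others + pseudocount))
    return DEMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def validate(dem: DEMatrix, catalog=None) -> dict:
    """Summarize a DEMatrix: sizes, missingness, catalog-gene coverage."""
    report = {
        "n_genes": len(dem.genes),
        "n_contexts": len(dem.contexts),
        "n_missing": dem.n_missing,
    }
    if catalog is not None:
        cat_genes = catalog.genes
        present = len(cat_genes & set(dem.genes))
        report["catalog_gene_fraction"] = present / len(cat_genes) if cat_genes else 0.0
    return report


def write_wide_tsv(dem: DEMatrix, path: str | Path) -> None:
    dem.data.to_csv(path, sep="\t", na_rep="", index_label="gene")


def write_marker_table(
    dem: DEMatrix,
    path: str | Path,
    gene_col: str = "gene",
    context_col: str = "cluster",
    value_col: str = "avg_log2FC",
) -> None:
    """Write the long (gene, cluster, value) form; missing entries are omitted."""
    long = dem.data.stack().rename(value_col).reset_index()
    long.columns = [gene_col, context_col, value_col]
    long.to_csv(path, sep="\t", index=False)
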