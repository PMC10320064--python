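"""Cell-type annotation of cell subsets via cell-type process groups.

A *cell-type process group* is the set of processes associated with one cell
type (e.g. 'Schwann cell differentiation' and 'Schwann cell development' for
Schwann cells). Per cell subset, the group's score is the plain mean of the
ProAct scores of its member processes; ranking the groups by score suggests
candidate identities for the subset.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .scoring import ScoreTable

__all__ = [
    "CellTypeGroups",
    "load_groups",
    "group_scores",
    "rank_cell_types",
    "CellTypeAnnotator",
    "write_groups_tsv",
]

logger = logging.getLogger(__name__)

_GROUP_HEADER_TOKENS = {"cell_type", "celltype", "cell type", "process_id", "process", "go_id", "term"}

GROUP_RECORD_COLUMNS = ["subset", "cell_type", "group_score", "n_processes_scored", "rank"]


class CellTypeGroups:
    """Mapping cell-type label → set of process ids.

    A process may belong to several groups; every group must be non-empty.
    """

    def __init__(self, groups: Mapping[str, Iterable[str]], source: str = "") -> None:
        self._groups: dict[str, frozenset[str]] = {}
        for label, pids in groups.items():
            if not label:
                raise ValueError("cell-type labels must be non-empty")
            if label in self._groups:
                raise ValueError(f"duplicate cell-type label {label!r}")
            pidset = frozenset(pids)
            if not pidset:
                raise ValueError(f"cell-type group {label!r} is empty")
            self._groups[label] = pidset
        if not self._groups:
            raise ValueError("no cell-type groups given")
        self.source = source

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, label: object) -> bool:
        return label in self._groups

    def __getitem__(self, label: str) -> frozenset[str]:
        return self._groups[label]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CellTypeGroups({len(self)} cell types, source={self.source!r})"

    @property
    def labels(self) -> list[str]:
        return list(self._groups)

    @property
    def groups(self) -> dict[str, frozenset[str]]:
        return dict(self._groups)

    @property
    def process_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for pids in self._groups.values():
            out |= pids
        return frozenset(out)


def load_groups(path: str | Path) -> CellTypeGroups:
    """Read a two-column (cell_type, process_id) TSV; header optional."""
    groups: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"malformed group table at line {lineno}: expected "
                    f"(cell_type, process_id), got {line!r}"
                )
            if lineno == 1 and any(f.strip().lower() in _GROUP_HEADER_TOKENS for f in fields):
                continue
            groups.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    if not groups:
        raise ValueError(f"no cell-type groups parsed from {path}")
    return CellTypeGroups(groups, source=str(path))


def write_groups_tsv(groups: CellTypeGroups, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_type\tprocess_id\n")
        for label in groups.labels:
            for pid in sorted(groups[label]):
                fh.write(f"{label}\t{pid}\n")


def _group_stats(
    score_matrix: pd.DataFrame, groups: CellTypeGroups
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (subset, cell type): mean of available member scores and the count.

    ``score_matrix`` is contexts × processes; NaN scores (unavailable) are
    skipped rather than treated as zero.
    """
    pids = set(score_matrix.columns)
    means: dict[str, pd.Series] = {}
    counts: dict[str, pd.Series] = {}
    for label in sorted(groups.labels):
        members = sorted(groups[label] & pids)
        if not members:
            continue
        block = score_matrix[members]
        n = block.notna().sum(axis=1)
        means[label] = block.mean(axis=1, skipna=True)
        counts[label] = n
    if not means:
        raise ValueError("no overlap between any cell-type group and the score table")
    return pd.DataFrame(means), pd.DataFrame(counts)


class CellTypeAnnotator(TransformerMixin, BaseEstimator):
    """Rank candidate cell-type identities for cell subsets.

    A scikit-learn-style estimator over a contexts × processes score matrix
    (the output of :class:`~proact.scoring.ProcessActivityScorer.transform`):
    ``transform`` yields the contexts × cell-types group-score matrix and
    ``predict`` the top-ranked cell-type label per subset. Group scores are
    plain (untrimmed) means over member processes with available scores;
    members without a score reduce the count instead of contributing zeros.
    """

    def __init__(self, groups: CellTypeGroups | None = None) -> None:
        self.groups = groups

    def fit(self, X, y=None) -> "CellTypeAnnotator":
        if self.groups is None:
            raise ValueError("CellTypeGroups are required (groups=...)")
        X = self._as_matrix(X)
        means, _ = _group_stats(X, self.groups)  # validates overlap
        self.cell_types_ = list(means.columns)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _as_matrix(X) -> pd.DataFrame:
        if isinstance(X, ScoreTable):
            return X.matrix().T
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError("X must be a ScoreTable or a contexts x processes DataFrame")

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.cell_types_, dtype=object)

    def transform(self, X) -> pd.DataFrame:
        """Contexts × cell-types matrix of group scores (NaN if none scored)."""
        if not hasattr(self, "cell_types_"):
            raise RuntimeError("this CellTypeAnnotator instance is not fitted yet")
        means, _ = _group_stats(self._as_matrix(X), self.groups)
        return means.reindex(columns=self.cell_types_)

    def predict(self, X) -> np.ndarray:
        """Top-ranked cell-type label per subset (ties broken by label)."""
        means = self.transform(X)
        labels = []
        for subset, row in means.iterrows():
            avail = row.dropna()
            if avail.empty:
                raise ValueError(f"no cell-type group scored in subset {subset!r}")
            # stable sort: ties resolve to the lexicographically first label
            labels.append(avail.sort_index().sort_values(ascending=False, kind="stable").index[0])
        return np.asarray(labels, dtype=object)


def group_scores(table: ScoreTable, groups: CellTypeGroups) -> pd.DataFrame:
    """Score and rank every cell-type group in every subset.

    Returns a frame with columns subset, cell_type, group_score,
    n_processes_scored, rank (1-based, descending score, ties broken by
    cell-type label). Groups with no scored member in a subset are omitted
    with a logged note.
    """
    matrix = table.matrix().T  # subsets × processes
    means, counts = _group_stats(matrix, groups)
    rows = []
    for subset in matrix.index:
        sub = pd.DataFrame(
            {"group_score": means.loc[subset], "n_processes_scored": counts.loc[subset]}
        )
        scored = sub[sub["n_processes_scored"] >= 1].copy()
        dropped = sub.index.difference(scored.index)
        for label in dropped:
            logger.info("subset %s: group %s has no scored member, omitted", subset, label)
        scored = scored.sort_index().sort_values(
            "group_score", ascending=False, kind="stable"
        )
        scored["rank"] = np.arange(1, len(scored) + 1)
        for label, r in scored.iterrows():
            rows.append(
                (subset, label, float(r["group_score"]), int(r["n_processes_scored"]),
                 int(r["rank"]))
            )
    return pd.DataFrame(rows, columns=GROUP_RECORD_COLUMNS)


def rank_cell_types(records: pd.DataFrame, subset: str, top_k: int = 10) -> pd.DataFrame:
    """The ``top_k`` candidate identities for ``subset``, in rank order."""
    if subset not in set(records["subset"]):
        raise ValueError(f"unknown subset {subset!r}")
    sub = records[records["subset"] == subset].sort_values("rank")
    return sub.head(top_k).reset_index(drop=True)
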