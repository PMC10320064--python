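"""Preferential process-activity (ProAct/TiPA) scores.

The score of process *p* in context *c* is the outlier-trimmed mean of the
differential-expression values in *c* of the genes annotated to *p*. Positive
scores mark processes preferentially active in that context relative to the
others; negative scores mark downregulated processes. Significance comes from
a gene-sampling null: random same-size gene sets drawn from the genes observed
in the same context, summarized as a z-score and a two-sided normal p-value,
then Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import ProcessCatalog, filter_catalog
from .demat import DEMatrix

__all__ = [
    "TrimConfig",
    "trimmed_mean",
    "ScoreTable",
    "ProcessActivityScorer",
    "compute_scores",
    "score_significance",
    "bh_adjust",
]

_RECORD_COLUMNS = [
    "process_id", "process_name", "context", "score",
    "n_genes_annotated", "n_genes_observed", "n_genes_used",
    "z", "p", "q", "degenerate_null",
]


@dataclass(frozen=True)
class TrimConfig:
    """How the per-process mean is trimmed.

    ``"extreme"`` (default) drops the ``ceil(fraction * n)`` values most
    deviant from the median in *either* direction — aimed at the occasional
    gene dramatically differentially expressed relative to the rest of its
    process. ``ceil`` ensures that even small processes (n = 3–9) trim one
    outlier. ``"tails"`` is the classical symmetric trimmed mean, dropping
    ``floor(fraction * n / 2)`` values from each end. ``"none"`` is the plain
    mean.
    """

    fraction: float = 0.10
    mode: str = "extreme"

    def __post_init__(self) -> None:
        if self.mode not in ("extreme", "tails", "none"):
            raise ValueError(f"unknown trim mode {self.mode!r}")
        if self.mode == "tails" and not 0 <= self.fraction < 0.5:
            raise ValueError("tails mode requires 0 <= fraction < 0.5")
        if self.mode == "extreme" and not 0 <= self.fraction < 1:
            raise ValueError("extreme mode requires 0 <= fraction < 1")


def trimmed_mean(values: Sequence[float], cfg: TrimConfig = TrimConfig()) -> tuple[float, int]:
    """Outlier-trimmed mean of ``values`` under ``cfg``; returns (mean, n_used).

    If trimming would remove every value, the plain mean is returned with
    ``n_used = n``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if not np.isfinite(v).all():
        raise ValueError("values must all be finite")
    n = v.size
    if cfg.mode == "none" or cfg.fraction == 0:
        return float(v.mean()), n
    if cfg.mode == "extreme":
        k = math.ceil(cfg.fraction * n)
        if k >= n:
            return float(v.mean()), n
        dev = np.abs(v - np.median(v))
        # Most extreme first; ties by larger |v|, then by input order.
        order = np.lexsort((np.arange(n), -np.abs(v), -dev))
        keep = np.sort(order[k:])
        return float(v[keep].mean()), n - k
    # tails
    d = math.floor(cfg.fraction * n / 2)
    if 2 * d >= n:
        return float(v.mean()), n
    s = np.sort(v)
    return float(s[d : n - d].mean()), n - 2 * d


def _trimmed_mean_rows(V: np.ndarray, cfg: TrimConfig) -> np.ndarray:
    """Row-wise trimmed mean of a 2-D array (same semantics as trimmed_mean)."""
    r, n = V.shape
    if cfg.mode == "none" or cfg.fraction == 0:
        return V.mean(axis=1)
    if cfg.mode == "extreme":
        k = math.ceil(cfg.fraction * n)
        if k >= n:
            return V.mean(axis=1)
        dev = np.abs(V - np.median(V, axis=1, keepdims=True))
        cols = np.broadcast_to(np.arange(n), V.shape)
        order = np.lexsort((cols, -np.abs(V), -dev), axis=1)
        keep = np.sort(order[:, k:], axis=1)
        return np.take_along_axis(V, keep, axis=1).mean(axis=1)
    d = math.floor(cfg.fraction * n / 2)
    if 2 * d >= n:
        return V.mean(axis=1)
    S = np.sort(V, axis=1)
    return S[:, d : n - d].mean(axis=1)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    After ascending sort, q(i) = min_{j >= i} p(j)·m/j, clipped to <= 1 and
    mapped back to input order. Ties in p receive equal q regardless of sort
    order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (~np.isfinite(p)).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class ScoreTable:
    """Per (process, context) score records plus the configuration that made them.

    Columns of ``records``: process_id, process_name, context, score,
    n_genes_annotated, n_genes_observed, n_genes_used, z, p, q,
    degenerate_null. ``score`` is NaN where fewer than ``min_genes`` values
    were observed (emitted, flagged unavailable, never silently dropped).
    """

    records: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def process_ids(self) -> list[str]:
        return list(pd.unique(self.records["process_id"]))

    @property
    def contexts(self) -> list[str]:
        return list(pd.unique(self.records["context"]))

    def matrix(self) -> pd.DataFrame:
        """Processes × contexts score matrix (NaN where unavailable)."""
        mat = self.records.pivot(index="process_id", columns="context", values="score")
        return mat.reindex(index=self.process_ids, columns=self.contexts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in self.params.items():
                fh.write(f"# {key}={json.dumps(val)}\n")
            self.records.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        params: dict = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    params[key.strip()] = json.loads(val)
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            records = pd.read_csv(fh, sep="\t")
        if "degenerate_null" in records:
            records["degenerate_null"] = records["degenerate_null"].astype(bool)
        return cls(records=records, params=params)


class ProcessActivityScorer(TransformerMixin, BaseEstimator):
    """Transform a contexts × genes differential-expression frame into
    contexts × processes preferential-activity scores.

    Follows the scikit-learn transformer protocol: samples (rows) are
    contexts, input features are genes, output features are processes.
    A :class:`~proact.demat.DEMatrix` (genes × contexts) is accepted anywhere
    a frame is and transposed internally.

    Parameters
    ----------
    catalog : ProcessCatalog
        Process → gene-set annotations.
    trim_fraction, trim_mode
        See :class:`TrimConfig`; defaults trim the 10% most extreme values.
    min_genes, max_genes
        Expressed-gene band: processes with fewer than ``min_genes`` or more
        than ``max_genes`` genes present in the matrix are not scored.
    filter_expressed : bool
        If False, skip the band filter (assume the catalog is pre-filtered).
    n_null : int or None
        Number of random gene sets per null distribution; None disables
        significance estimation in :meth:`score_table`.
    bh_family : {"global", "per_context"}
        Whether BH adjustment pools all (process, context) records or runs
        within each context.
    random_state : int or None
        Seed for the null draws.

    Attributes
    ----------
    terms_ : list of ProcessTerm
        Scored processes after filtering.
    catalog_ : ProcessCatalog
        The (possibly band-filtered) catalog used for scoring.
    feature_names_in_ : ndarray of gene labels seen in ``fit``.
    """

    def __init__(
        self,
        catalog: ProcessCatalog | None = None,
        *,
        trim_fraction: float = 0.10,
        trim_mode: str = "extreme",
        min_genes: int = 3,
        max_genes: int = 100,
        filter_expressed: bool = True,
        n_null: int | None = None,
        bh_family: str = "global",
        random_state: int | None = None,
    ) -> None:
        self.catalog = catalog
        self.trim_fraction = trim_fraction
        self.trim_mode = trim_mode
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.filter_expressed = filter_expressed
        self.n_null = n_null
        self.bh_family = bh_family
        self.random_state = random_state

    # -- plumbing ---------------------------------------------------------

    @staticmethod
    def _as_samples_frame(X) -> pd.DataFrame:
        if isinstance(X, DEMatrix):
            return X.to_samples_frame()
        if isinstance(X, pd.DataFrame):
            DEMatrix(X.T)  # reuse the container's validation
            return X
        raise TypeError(
            "X must be a DEMatrix or a gene-labelled DataFrame (contexts as rows)"
        )

    def _trim_config(self) -> TrimConfig:
        return TrimConfig(fraction=self.trim_fraction, mode=self.trim_mode)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None) -> "ProcessActivityScorer":
        if self.catalog is None:
            raise ValueError("a ProcessCatalog is required (catalog=...)")
        if self.bh_family not in ("global", "per_context"):
            raise ValueError(f"unknown bh_family {self.bh_family!r}")
        self._trim_config()  # validates trim parameters
        df = self._as_samples_frame(X)
        genes = set(df.columns)
        if not (self.catalog.genes & genes):
            raise ValueError("no catalog gene is present in the expression matrix")
        if self.filter_expressed:
            cat = filter_catalog(self.catalog, genes, self.min_genes, self.max_genes)
            if len(cat) == 0:
                raise ValueError(
                    f"no process has {self.min_genes}-{self.max_genes} expressed genes"
                )
        else:
            cat = self.catalog
        self.catalog_ = cat
        self.terms_ = cat.terms
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        self._check_fitted()
        return np.asarray([t.process_id for t in self.terms_], dtype=object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "terms_"):
            raise RuntimeError("this ProcessActivityScorer instance is not fitted yet")

    def transform(self, X) -> pd.DataFrame:
        """Contexts × processes score matrix for ``X``."""
        table = self.score_table(X, significance=False)
        return table.matrix().T

    def score_table(self, X, *, significance: bool | None = None) -> ScoreTable:
        """Full per (process, context) record table for ``X``.

        ``significance`` defaults to ``n_null is not None``.
        """
        self._check_fitted()
        df = self._as_samples_frame(X)
        if list(df.columns) != list(self.feature_names_in_):
            raise ValueError("gene columns of X do not match those seen during fit")
        cfg = self._trim_config()
        records = _compute_records(df, self.terms_, cfg, self.min_genes)
        params = {
            "trim_fraction": self.trim_fraction,
            "trim_mode": self.trim_mode,
            "min_genes": self.min_genes,
            "max_genes": self.max_genes,
        }
        if significance is None:
            significance = self.n_null is not None
        if significance:
            n_null = self.n_null if self.n_null is not None else 1000
            rng = np.random.default_rng(self.random_state)
            records = _attach_significance(df, records, cfg, n_null, rng, self.bh_family)
            params.update(n_null=n_null, seed=self.random_state, bh_family=self.bh_family)
        return ScoreTable(records=records, params=params)


def _compute_records(
    samples: pd.DataFrame,
    terms,
    cfg: TrimConfig,
    min_genes: int,
) -> pd.DataFrame:
    """Score every (term, context) pair of a contexts × genes frame."""
    vals = samples.to_numpy(dtype=float).T  # genes × contexts
    gene_pos = {g: i for i, g in enumerate(samples.columns)}
    term_idx = [
        np.fromiter(
            sorted(gene_pos[g] for g in t.genes if g in gene_pos), dtype=int
        )
        for t in terms
    ]
    rows = []
    for j, context in enumerate(samples.index):
        col = vals[:, j]
        for t, idx in zip(terms, term_idx):
            tv = col[idx]
            obs = tv[np.isfinite(tv)]
            n_obs = obs.size
            if n_obs >= max(min_genes, 1):
                score, n_used = trimmed_mean(obs, cfg)
            else:
                score, n_used = np.nan, 0
            rows.append(
                (t.process_id, t.name, context, score, t.n_genes, n_obs, n_used,
                 np.nan, np.nan, np.nan, False)
            )
    rec = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    return rec


def _attach_significance(
    samples: pd.DataFrame,
    records: pd.DataFrame,
    cfg: TrimConfig,
    n_null: int,
    rng: np.random.Generator,
    bh_family: str = "global",
) -> pd.DataFrame:
    """Gene-sampling null: z, two-sided p, BH q per scored record.

    For each record with k observed genes, n_null random size-k gene sets are
    drawn (uniform, without replacement) from the genes observed in the same
    context and scored with the same trimmed mean; null distributions are
    cached per (context, k). A zero-variance null flags the record degenerate
    (z = 0, p = 1).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rec = records.copy()
    vals = samples.to_numpy(dtype=float).T  # genes × contexts
    z = np.full(len(rec), np.nan)
    p = np.full(len(rec), np.nan)
    degen = np.zeros(len(rec), dtype=bool)
    ctx_index = {c: j for j, c in enumerate(samples.index)}
    scored = rec["score"].notna().to_numpy()
    for context in samples.index:  # fixed column order keeps draws reproducible
        j = ctx_index[context]
        col = vals[:, j]
        obs_vals = col[np.isfinite(col)]
        m = obs_vals.size
        in_ctx = (rec["context"] == context).to_numpy() & scored
        if not in_ctx.any():
            continue
        for k in sorted(rec.loc[in_ctx, "n_genes_observed"].unique()):
            k = int(k)
            sel = in_ctx & (rec["n_genes_observed"] == k).to_numpy()
            if k >= m:
                null_scores = np.full(n_null, trimmed_mean(obs_vals, cfg)[0])
            else:
                idx = _sample_index_sets(rng, n_null, m, k)
                null_scores = _trimmed_mean_rows(obs_vals[idx], cfg)
            mu = null_scores.mean()
            sd = null_scores.std(ddof=1)
            if sd > 0:
                zz = (rec.loc[sel, "score"].to_numpy() - mu) / sd
                z[sel] = zz
                p[sel] = 2.0 * stats.norm.sf(np.abs(zz))
            else:
                z[sel] = 0.0
                p[sel] = 1.0
                degen[sel] = True
    rec["z"] = z
    rec["p"] = p
    rec["degenerate_null"] = degen
    q = np.full(len(rec), np.nan)
    if bh_family == "per_context":
        for context in samples.index:
            sel = (rec["context"] == context).to_numpy() & np.isfinite(p)
            if sel.any():
                q[sel] = bh_adjust(p[sel])
    else:
        sel = np.isfinite(p)
        if sel.any():
            q[sel] = bh_adjust(p[sel])
    rec["q"] = q
    return rec


def _sample_index_sets(
    rng: np.random.Generator, n_draws: int, m: int, k: int
) -> np.ndarray:
    """n_draws uniform random k-subsets of range(m), as an (n_draws, k) array."""
    if n_draws * m <= 20_000_000:
        keys = rng.random((n_draws, m))
        return np.argpartition(keys, k - 1, axis=1)[:, :k]
    return np.stack([rng.choice(m, size=k, replace=False) for _ in range(n_draws)])


# -- functional wrappers over the estimator --------------------------------


def compute_scores(
    dem: DEMatrix,
    catalog: ProcessCatalog,
    cfg: TrimConfig | None = None,
    *,
    min_genes: int = 3,
) -> ScoreTable:
    """Score every (process, context) pair of ``dem`` against ``catalog``.

    The catalog is assumed to be already filtered to the expressed band;
    records observing fewer than ``min_genes`` genes are emitted with the
    score flagged unavailable (NaN).
    """
    cfg = cfg or TrimConfig()
    scorer = ProcessActivityScorer(
        catalog,
        trim_fraction=cfg.fraction,
        trim_mode=cfg.mode,
        min_genes=min_genes,
        filter_expressed=False,
    ).fit(dem)
    return scorer.score_table(dem, significance=False)


def score_significance(
    dem: DEMatrix,
    table: ScoreTable,
    n_null: int = 1000,
    seed: int | None = None,
    *,
    bh_family: str = "global",
) -> ScoreTable:
    """Attach z, p and BH q to an existing :class:`ScoreTable`.

    Uses the trim configuration frozen into ``table.params`` so the null is
    scored exactly as the observed sets were.
    """
    cfg = TrimConfig(
        fraction=table.params.get("trim_fraction", 0.10),
        mode=table.params.get("trim_mode", "extreme"),
    )
    rng = np.random.default_rng(seed)
    records = _attach_significance(
        dem.to_samples_frame(), table.records, cfg, n_null, rng, bh_family
    )
    params = dict(table.params)
    params.update(n_null=n_null, seed=seed, bh_family=bh_family)
    return ScoreTable(records=records, params=params)
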