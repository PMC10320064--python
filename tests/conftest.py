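import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from proact import DEMatrix, ProcessCatalog, ProcessTerm

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def small_catalog() -> ProcessCatalog:
    """Five hand-built terms over a 9-gene universe."""
    return ProcessCatalog(
        [
            ProcessTerm("GO:1", "muscle contraction", frozenset({"DMD", "TTN", "ACTA1"})),
            ProcessTerm("GO:2", "lipid remodeling", frozenset({"APOA1", "LPL", "DMD"})),
            ProcessTerm("GO:3", "glyoxylate catabolism", frozenset({"AGXT", "HAO1"})),
            ProcessTerm("GO:4", "myelination", frozenset({"MPZ", "PMP22", "DMD"})),
            ProcessTerm("GO:5", "platelet formation", frozenset({"TTN", "LPL"})),
        ],
        source="fixture",
    )


@pytest.fixture
def small_dem() -> DEMatrix:
    """Complete 9-gene x 3-context matrix with easy hand-checkable values."""
    genes = ["DMD", "TTN", "ACTA1", "APOA1", "LPL", "AGXT", "HAO1", "MPZ", "PMP22"]
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(0.0, 0.5, size=(9, 3)),
        index=genes,
        columns=["muscle", "liver", "nerve"],
    )
    return DEMatrix(data)


def brute_force_trimmed_mean(values, fraction=0.10, mode="extreme"):
    """Independent trimmed-mean oracle: explicit sort-and-drop enumeration."""
    import math

    v = list(map(float, values))
    n = len(v)
    if mode == "none" or fraction == 0:
        return float(np.mean(np.asarray(v))), n
    if mode == "extreme":
        k = math.ceil(fraction * n)
        if k >= n:
            return float(np.mean(np.asarray(v))), n
        med = float(np.median(np.asarray(v)))
        ranked = sorted(range(n), key=lambda i: (-abs(v[i] - med), -abs(v[i]), i))
        kept = sorted(set(range(n)) - set(ranked[:k]))
        return float(np.mean(np.asarray([v[i] for i in kept]))), n - k
    d = math.floor(fraction * n / 2)
    if 2 * d >= n:
        return float(np.mean(np.asarray(v))), n
    s = sorted(v)
    return float(np.mean(np.asarray(s[d : n - d]))), n - 2 * d


def brute_force_bh(pvalues):
    """Textbook step-up BH: q(i) = min_{j>=i} p_(j) * m / j, in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
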