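"""One-vs-rest Mann-Whitney differential expression and DEG-list selection.

For each cluster, every gene's expression values are split into the cluster
group and the all-other-spots group and compared with a Mann-Whitney U test:
expression values are jointly ranked (average ranks for ties), rank sums
R_x / R_y give the U statistics

    U_x = R_x - n_x (n_x + 1) / 2,      U_x + U_y = n_x n_y,

and min(U_x, U_y) drives a two-sided p-value via the normal approximation
with tie and continuity corrections.  Genes are ranked per cluster by
ascending p-value.

The DEG-list selection then scans a grid of per-cluster list sizes: for each
size the union over clusters of the top genes is taken and the non-zero rate
of the expression sub-matrix restricted to that union is computed.  Sizes
whose rate falls inside the target window (0.3-0.4 by default) are kept —
small enough to exclude noisy, dropout-heavy genes, large enough to retain
informative features.  Each surviving list later drives one imputation and
clustering round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .clustering import ClusterAssignment
from .dataset import NormalizedMatrix
from .preprocess import nonzero_rate

__all__ = [
    "RankSumResult",
    "DEGSelection",
    "rank_sum_test",
    "deg_per_cluster",
    "select_deg_lists",
    "DEFAULT_SIZE_GRID",
    "DEFAULT_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZE_GRID = (25, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500)
DEFAULT_WINDOW = (0.3, 0.4)


@dataclass
class RankSumResult:
    """Mann-Whitney U test summary for one two-group comparison."""

    U_x: float
    U_y: float
    n_x: int
    n_y: int
    R_x: float
    R_y: float
    p_value: float


def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t) for one 1-D sample."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def _p_from_u(u_min: np.ndarray, n_x, n_y, tie_term, N) -> np.ndarray:
    """Two-sided p from min(U_x, U_y), normal approximation.

    Variance uses the tie correction; the continuity correction shifts the
    statistic half a unit toward the mean.  Fully tied data (zero variance)
    yields p = 1.
    """
    mu = n_x * n_y / 2.0
    var = n_x * n_y / 12.0 * ((N + 1.0) - tie_term / (N * (N - 1.0)))
    var = np.asarray(var, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u_min - mu + 0.5) / np.sqrt(var)
    p = np.where(var <= 0, 1.0, 2.0 * norm.cdf(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def rank_sum_test(x, y) -> RankSumResult:
    """Mann-Whitney U test of two value groups (see module docs)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n_x, n_y = x.size, y.size
    if n_x < 1 or n_y < 1:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    R_x = float(ranks[:n_x].sum())
    R_y = float(ranks[n_x:].sum())
    U_x = R_x - n_x * (n_x + 1) / 2.0
    U_y = R_y - n_y * (n_y + 1) / 2.0
    p = float(
        _p_from_u(min(U_x, U_y), n_x, n_y, _tie_term(combined), n_x + n_y)
    )
    return RankSumResult(U_x=U_x, U_y=U_y, n_x=n_x, n_y=n_y, R_x=R_x, R_y=R_y, p_value=p)


def _per_cluster_tables(values: np.ndarray, labels: np.ndarray):
    """Vectorized one-vs-rest test for every (cluster, gene) pair.

    The combined sample is all spots regardless of the split, so the joint
    per-gene ranking (and its tie term) is shared across clusters.

    Returns (clusters, p, rank_biserial) with p and r of shape
    (n_clusters, n_genes).
    """
    n, g = values.shape
    ranks = rankdata(values, axis=0)
    tie = np.empty(g)
    for j in range(g):  # per-gene tie census; g is a few thousand at most
        tie[j] = _tie_term(values[:, j])
    clusters = np.unique(labels)
    p = np.empty((clusters.size, g))
    rb = np.empty((clusters.size, g))
    for i, c in enumerate(clusters):
        mask = labels == c
        n_x = int(mask.sum())
        n_y = n - n_x
        if n_x < 2:
            p[i] = np.nan
            rb[i] = np.nan
            continue
        R_x = ranks[mask].sum(axis=0)
        U_x = R_x - n_x * (n_x + 1) / 2.0
        U_y = n_x * n_y - U_x
        p[i] = _p_from_u(np.minimum(U_x, U_y), n_x, n_y, tie, n)
        rb[i] = 2.0 * U_x / (n_x * n_y) - 1.0
    return clusters, p, rb


def deg_per_cluster(
    x: NormalizedMatrix, c: ClusterAssignment, size: int
) -> dict[int, list[str]]:
    """Top ``size`` differentially expressed genes for each cluster.

    Genes are ordered by ascending one-vs-rest p-value, ties broken by
    larger |rank-biserial| effect then by gene index.  Clusters with fewer
    than 2 spots are skipped with a warning.
    """
    if size > x.n_genes:
        raise ValueError(f"size {size} exceeds gene count {x.n_genes}")
    labels = np.asarray(c.labels)
    clusters, p, rb = _per_cluster_tables(x.values, labels)
    out: dict[int, list[str]] = {}
    for i, cl in enumerate(clusters):
        if np.isnan(p[i]).all():
            logger.warning("cluster %s has < 2 spots; skipped in DEG ranking", cl)
            continue
        order = np.lexsort((np.arange(x.n_genes), -np.abs(rb[i]), p[i]))
        out[int(cl)] = [x.gene_ids[j] for j in order[:size]]
    return out


@dataclass
class DEGSelection:
    """Per-cluster DEG rankings and the list sizes surviving the rate window."""

    per_cluster_rankings: dict[int, list[str]]
    candidate_sizes: list[int]
    #: (size, union gene list, non-zero rate) for each kept size
    selected: list[tuple[int, list[str], float]]
    window: tuple[float, float] = DEFAULT_WINDOW
    fallback_used: bool = False

    @property
    def gene_lists(self) -> list[list[str]]:
        return [genes for _, genes, _ in self.selected]


def select_deg_lists(
    x: NormalizedMatrix,
    c: ClusterAssignment,
    size_grid=DEFAULT_SIZE_GRID,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> DEGSelection:
    """Pick the DEG list sizes whose union sub-matrix rate falls in ``window``.

    For each candidate per-cluster size, the union of top genes across
    clusters is formed (deduplicated, gene order of the matrix) and the
    non-zero rate of the restricted matrix computed.  If no size lands in
    the window, the single size with the rate closest to the window is kept
    as a fallback (logged).
    """
    sizes = sorted({min(int(s), x.n_genes) for s in size_grid if s > 0})
    if not sizes:
        raise ValueError("size grid is empty")
    lo, hi = window
    rankings = deg_per_cluster(x, c, size=x.n_genes)
    gene_pos = {g: j for j, g in enumerate(x.gene_ids)}
    selected: list[tuple[int, list[str], float]] = []
    all_entries: list[tuple[int, list[str], float]] = []
    for size in sizes:
        union: set[str] = set()
        for genes in rankings.values():
            union.update(genes[:size])
        ordered = sorted(union, key=gene_pos.__getitem__)
        cols = [gene_pos[g] for g in ordered]
        rate = nonzero_rate(x.values[:, cols])
        all_entries.append((size, ordered, rate))
        if lo <= rate <= hi:
            selected.append((size, ordered, rate))
    fallback = False
    if not selected:
        def dist(entry):
            r = entry[2]
            return max(lo - r, r - hi, 0.0)
        best = min(all_entries, key=dist)
        selected = [best]
        fallback = True
        logger.warning(
            "no DEG list size lands in the %.2f-%.2f window; "
            "falling back to size %d (rate %.3f)", lo, hi, best[0], best[2]
        )
    return DEGSelection(
        per_cluster_rankings=rankings,
        candidate_sizes=sizes,
        selected=selected,
        window=(lo, hi),
        fallback_used=fallback,
    )
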