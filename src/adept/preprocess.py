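"""Spot/gene quality control and normalization.

The pipeline removes unusable spots, estimates a per-dataset gene min-count
threshold from the non-zero rate of the count matrix, filters genes, and then
library-size normalizes + log-transforms the surviving matrix.

The non-zero rate — the fraction of non-zero entries of an expression matrix —
is the data-quality statistic used throughout: sequencing platforms differ
drastically in sparsity, and filtering the lowest-total-count genes until the
matrix reaches a target rate (0.14 by default) brings datasets to a roughly
uniform quality before the autoencoder sees them.
"""

from __future__ import annotations

import logging

import numpy as np

from .dataset import NormalizedMatrix, QualityCurve, STDataset

__all__ = [
    "remove_outlier_spots",
    "nonzero_rate",
    "estimate_min_count",
    "filter_genes",
    "normalize",
]

logger = logging.getLogger(__name__)

#: Min-count floor applied when a matrix already meets the target rate:
#: high-quality data only sheds genes with a total count below 5.
MIN_COUNT_FLOOR = 5
DEFAULT_TARGET_RATE = 0.14


def remove_outlier_spots(d: STDataset, graph_k: int = 6) -> STDataset:
    """Drop spots outside the tissue and spots without annotation.

    Out-of-tissue spots (Visium ``in_tissue == 0``) and, when ground-truth
    labels are attached, spots whose label is missing/NA are removed; these
    are exactly the spots with poor sequencing quality and no usable
    neighbors.  Idempotent.
    """
    keep = np.ones(d.n_spots, dtype=bool)
    if d.in_tissue is not None:
        keep &= d.in_tissue
    if d.labels is not None:
        def _is_na(x) -> bool:
            if x is None:
                return True
            if isinstance(x, float) and np.isnan(x):
                return True
            return str(x).strip().lower() in {"", "na", "nan", "none"}

        keep &= np.array([not _is_na(l) for l in d.labels])
    if not keep.any():
        raise ValueError("all spots removed by outlier filtering")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d outlier spot(s)", n_removed)
    return d.subset_spots(np.flatnonzero(keep))


def nonzero_rate(m: np.ndarray) -> float:
    """Fraction of non-zero entries of a count or normalized matrix."""
    m = np.asarray(m)
    if m.size == 0:
        raise ValueError("non-zero rate of an empty matrix is undefined")
    return float(np.count_nonzero(m)) / m.size


def estimate_min_count(
    d: STDataset,
    target_rate: float = DEFAULT_TARGET_RATE,
    floor: int = MIN_COUNT_FLOOR,
    scan_ceiling: int = 1000,
) -> tuple[int, QualityCurve]:
    """Estimate the per-gene min-count threshold from the non-zero rate.

    Scans integer thresholds ``t = 0, 1, 2, ...``; at each, genes with total
    count ``< t`` are (virtually) removed and the non-zero rate of the
    remaining matrix recorded.  The returned threshold is the smallest ``t``
    reaching ``target_rate`` — removing as few genes as possible.  If the
    unfiltered matrix already meets the target the floor threshold (5) is
    returned, so high-quality data still sheds its near-empty genes.

    Image-based (STARmap) datasets skip this step in the pipeline: their
    gene panels are small and curated.

    Returns ``(threshold, curve)`` where ``curve`` records the scan.
    """
    if d.platform == "starmap":
        raise ValueError("min-count estimation is skipped for STARmap data")
    counts = d.counts
    n_spots, n_genes = counts.shape
    gene_sums = counts.sum(axis=0)
    gene_nnz = (counts > 0).sum(axis=0)

    # rate(t) over genes with sum >= t, via a single sort + suffix sums
    order = np.argsort(gene_sums, kind="stable")
    sorted_sums = gene_sums[order]
    suffix_nnz = np.cumsum(gene_nnz[order][::-1])[::-1]  # nnz of genes kept at cut i

    thresholds: list[int] = []
    rates: list[float] = []
    removed: list[int] = []
    hit: int | None = None
    for t in range(0, scan_ceiling + 1):
        cut = int(np.searchsorted(sorted_sums, t, side="left"))
        n_keep = n_genes - cut
        if n_keep == 0:
            break
        rate = float(suffix_nnz[cut]) / (n_spots * n_keep)
        thresholds.append(t)
        rates.append(rate)
        removed.append(cut)
        if rate >= target_rate:
            hit = t
            break
    curve = QualityCurve(thresholds, rates, removed)
    if hit is None:
        raise ValueError(
            f"no threshold <= {scan_ceiling} reaches non-zero rate "
            f"{target_rate} (max achievable on scan: {max(rates):.4f})"
        )
    # unfiltered matrix already passes -> floor behavior
    threshold = floor if hit == 0 else hit
    return threshold, curve


def filter_genes(d: STDataset, min_count: int) -> STDataset:
    """Remove genes whose total count across all spots is below ``min_count``."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep = d.counts.sum(axis=0) >= min_count
    if not keep.any():
        raise ValueError(f"min_count={min_count} removes every gene")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filtered %d gene(s) with total count < %d", n_removed, min_count)
    return d.subset_genes(np.flatnonzero(keep))


def normalize(d: STDataset, target_sum: float | None = None) -> NormalizedMatrix:
    """Library-size normalize each spot, then apply log1p.

    Each spot's counts are scaled so its library size equals ``target_sum``
    (the median raw library size when not given), then ``log(1 + x)`` is
    applied.  Zeros map exactly to zeros, so the non-zero pattern of the raw
    counts is preserved.
    """
    counts = np.asarray(d.counts, dtype=float)
    lib = counts.sum(axis=1)
    zero_lib = np.flatnonzero(lib == 0)
    if zero_lib.size:
        bad = [d.spot_ids[i] for i in zero_lib[:5]]
        raise ValueError(f"spot(s) with zero total count: {bad}")
    if target_sum is None:
        target_sum = float(np.median(lib))
    values = np.log1p(counts * (target_sum / lib)[:, None])
    return NormalizedMatrix(
        values=values,
        gene_ids=list(d.gene_ids),
        spot_ids=list(d.spot_ids),
        provenance={"target_sum": target_sum, "n_genes": d.n_genes},
    )
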