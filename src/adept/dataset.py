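"""Core in-memory containers for spatial transcriptomics data.

A dataset is a spots x genes count matrix plus 2-D spot coordinates.  For
sequencing-based platforms (10x Visium) a "spot" covers 1-10 cells; for
image-based platforms (STARmap) each spot is a single cell.  Matrices are
stored spots x genes (observations in rows, the scanpy/anndata convention);
the genes x spots orientation used in some method descriptions is simply the
transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["STDataset", "NormalizedMatrix", "QualityCurve"]

VALID_PLATFORMS = ("visium", "starmap", "generic")


@dataclass
class STDataset:
    """Spots x genes counts with spatial coordinates and optional labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_spots, n_genes)``.
    spot_ids, gene_ids
        Row / column identifiers.  Spot ids must be unique; duplicated gene
        symbols are disambiguated by the loader with a ``-1``, ``-2`` suffix.
    coords
        Spot centroids, shape ``(n_spots, 2)``, in platform units (Visium
        array row/col, STARmap pixels).
    labels
        Optional ground-truth domain label per spot (``None`` entries mean
        un-annotated).
    platform
        One of ``"visium"``, ``"starmap"``, ``"generic"``.
    in_tissue
        Optional boolean flag per spot (Visium ``in_tissue`` column).
    """

    counts: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    coords: np.ndarray
    labels: Optional[list] = None
    platform: str = "generic"
    in_tissue: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.counts.shape
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot_ids for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {g} matrix columns")
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords shape {self.coords.shape}, expected {(n, 2)}")
        if len(set(self.spot_ids)) != n:
            dupes = sorted({s for s in self.spot_ids if self.spot_ids.count(s) > 1})
            raise ValueError(f"duplicated spot ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.counts)) or (self.counts < 0).any():
            raise ValueError("counts must be finite and non-negative")
        if self.platform not in VALID_PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match spot count")
        if self.in_tissue is not None:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if self.in_tissue.shape != (n,):
                raise ValueError("in_tissue length does not match spot count")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, idx: np.ndarray) -> "STDataset":
        idx = np.asarray(idx)
        return STDataset(
            counts=self.counts[idx],
            spot_ids=[self.spot_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            coords=self.coords[idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            platform=self.platform,
            in_tissue=None if self.in_tissue is None else self.in_tissue[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "STDataset":
        idx = np.asarray(idx)
        return STDataset(
            counts=self.counts[:, idx],
            spot_ids=list(self.spot_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            coords=self.coords,
            labels=self.labels,
            platform=self.platform,
            in_tissue=self.in_tissue,
        )


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log1p-transformed expression.

    Zeros are preserved exactly: an entry is 0 iff the raw count was 0, so
    the non-zero pattern (and hence the non-zero rate) of the raw matrix
    carries over unchanged.
    """

    values: np.ndarray  # (n_spots, n_genes) float
    gene_ids: list[str]
    spot_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("normalized values must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, gene_list: Sequence[str]) -> "NormalizedMatrix":
        """Sub-matrix over ``gene_list`` (order of the list is kept)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_list if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in gene_list]
        return NormalizedMatrix(
            values=self.values[:, cols],
            gene_ids=list(gene_list),
            spot_ids=list(self.spot_ids),
            provenance={**self.provenance, "restricted_to": len(cols)},
        )


@dataclass
class QualityCurve:
    """Scan of the gene min-count threshold against the non-zero rate.

    ``nonzero_rates[i]`` is the non-zero rate of the matrix after removing
    genes whose total count is below ``thresholds[i]``; ``genes_removed[i]``
    counts the genes dropped at that threshold.
    """

    thresholds: list[int]
    nonzero_rates: list[float]
    genes_removed: list[int]

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.nonzero_rates) == len(self.genes_removed)):
            raise ValueError("curve fields must have equal length")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if any(b < a for a, b in zip(self.genes_removed, self.genes_removed[1:])):
            raise ValueError("genes_removed must be non-decreasing")
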