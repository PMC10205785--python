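"""Readers and writers for spatial transcriptomics datasets.

Supported layouts
-----------------
visium
    A directory with the CellRanger triplet ``matrix.mtx[.gz]``,
    ``barcodes.tsv[.gz]``, ``features.tsv[.gz]`` plus a spot-position table
    (``tissue_positions_list.csv`` legacy 6-column headerless dialect, or
    headered ``tissue_positions.csv``), searched in the directory itself and
    in a ``spatial/`` subdirectory.  The matrix is stored genes x barcodes on
    disk and transposed to spots x genes in memory.
starmap / generic
    A single cells x genes delimited table (``counts.csv``/``.tsv``, cell ids
    in the first column, gene ids in the header) plus a coordinate table
    (``coords``/``positions``/``centroids`` ``.csv``/``.tsv`` with cell ids in
    the first column and two coordinate columns).

Ground-truth labels are 2-column delimited files (spot_id, label).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import STDataset

__all__ = [
    "load_dataset",
    "load_labels",
    "attach_labels",
    "write_labels",
    "write_matrix",
]

logger = logging.getLogger(__name__)


def _find(directory: Path, stems: list[str], exts: list[str]) -> Path | None:
    for sub in (directory, directory / "spatial"):
        for stem in stems:
            for ext in exts:
                p = sub / f"{stem}{ext}"
                if p.exists():
                    return p
    return None


def _require(directory: Path, stems: list[str], exts: list[str], what: str) -> Path:
    p = _find(directory, stems, exts)
    if p is None:
        raise FileNotFoundError(
            f"no {what} found under {directory} (looked for {stems} with {exts})"
        )
    return p


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _dedupe(names: list[str]) -> list[str]:
    """Disambiguate duplicated gene symbols with -1, -2, ... suffixes."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}-{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def _load_visium(directory: Path) -> STDataset:
    mtx = _require(directory, ["matrix"], [".mtx", ".mtx.gz"], "matrix.mtx")
    bar = _require(directory, ["barcodes"], [".tsv", ".tsv.gz"], "barcodes.tsv")
    feat = _require(directory, ["features", "genes"], [".tsv", ".tsv.gz"], "features.tsv")
    pos = _require(
        directory,
        ["tissue_positions_list", "tissue_positions"],
        [".csv", ".csv.gz"],
        "tissue positions table",
    )

    counts = scipy.io.mmread(str(mtx))
    if scipy.sparse.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts).T  # genes x barcodes on disk -> spots x genes
    barcodes = [l.split("\t")[0] for l in _read_lines(bar)]
    features = [l.split("\t")[1] if "\t" in l else l for l in _read_lines(feat)]
    features = _dedupe(features)
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )

    first = pd.read_csv(pos, nrows=1, header=None)
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    positions = pd.read_csv(pos, header=0 if has_header else None)
    positions.columns = [
        "barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col",
    ][: positions.shape[1]]
    positions = positions.set_index("barcode")

    in_pos = [b in positions.index for b in barcodes]
    if not any(in_pos):
        raise ValueError(
            f"no barcode overlap between matrix and positions "
            f"(matrix e.g. {barcodes[:3]}, positions e.g. {list(positions.index[:3])})"
        )
    dropped = int(len(barcodes) - sum(in_pos))
    if dropped:
        logger.info("dropping %d barcode(s) absent from the positions table", dropped)
    keep = np.flatnonzero(in_pos)
    barcodes = [barcodes[i] for i in keep]
    counts = counts[keep]
    tab = positions.loc[barcodes]
    coords = tab[["array_row", "array_col"]].to_numpy(dtype=float)
    return STDataset(
        counts=counts,
        spot_ids=barcodes,
        gene_ids=features,
        coords=coords,
        platform="visium",
        in_tissue=tab["in_tissue"].to_numpy(dtype=bool),
    )


def _load_table_pair(directory: Path, platform: str) -> STDataset:
    cnt = _require(
        directory, ["counts", "expression", "matrix"], [".csv", ".tsv"], "counts table"
    )
    crd = _require(
        directory,
        ["coords", "coordinates", "positions", "centroids"],
        [".csv", ".tsv"],
        "coordinate table",
    )
    sep_c = "\t" if cnt.suffix == ".tsv" else ","
    sep_p = "\t" if crd.suffix == ".tsv" else ","
    counts = pd.read_csv(cnt, sep=sep_c, index_col=0)
    coords = pd.read_csv(crd, sep=sep_p, index_col=0)
    cells = [c for c in counts.index.astype(str) if c in set(coords.index.astype(str))]
    dropped = counts.shape[0] - len(cells)
    if not cells:
        raise ValueError("no cell id overlap between counts and coordinate tables")
    if dropped:
        logger.info("dropping %d cell(s) absent from the coordinate table", dropped)
    counts.index = counts.index.astype(str)
    coords.index = coords.index.astype(str)
    counts = counts.loc[cells]
    xy = coords.loc[cells].iloc[:, :2].to_numpy(dtype=float)
    return STDataset(
        counts=counts.to_numpy(),
        spot_ids=cells,
        gene_ids=_dedupe([str(g) for g in counts.columns]),
        coords=xy,
        platform=platform,
    )


def load_dataset(path, platform: str = "generic") -> STDataset:
    """Load an ST dataset from ``path`` for the given platform.

    ``visium`` expects the MTX triplet + positions layout; ``starmap`` and
    ``generic`` expect a counts table + coordinate table (see module docs).
    """
    directory = Path(path)
    if not directory.exists():
        raise FileNotFoundError(f"dataset path does not exist: {directory}")
    if platform == "visium":
        return _load_visium(directory)
    return _load_table_pair(directory, platform)


def load_labels(path) -> dict[str, str]:
    """Read a 2-column (spot_id, label) TSV/CSV into a dict."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    tab = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if tab.shape[1] < 2:
        raise ValueError(f"label file {path} needs 2 columns (spot_id, label)")
    if tab.iloc[0, 0].strip().lower() in {"spot_id", "barcode", "cell_id", "id"}:
        tab = tab.iloc[1:]
    return dict(zip(tab.iloc[:, 0], tab.iloc[:, 1]))


def attach_labels(d: STDataset, labels: dict[str, str]) -> STDataset:
    """Attach ground-truth labels by spot id; missing spots get None."""
    return STDataset(
        counts=d.counts,
        spot_ids=d.spot_ids,
        gene_ids=d.gene_ids,
        coords=d.coords,
        labels=[labels.get(s) for s in d.spot_ids],
        platform=d.platform,
        in_tissue=d.in_tissue,
    )


def write_labels(path, spot_ids, labels) -> None:
    """Write (spot_id, label) pairs as a 2-column TSV."""
    pd.DataFrame({"spot_id": list(spot_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(path, values: np.ndarray, spot_ids, gene_ids) -> None:
    """Write a spots x genes matrix as dense CSV (``.csv``) or MatrixMarket (``.mtx``)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(np.asarray(values)))
    else:
        pd.DataFrame(np.asarray(values), index=list(spot_ids), columns=list(gene_ids)).to_csv(path)
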