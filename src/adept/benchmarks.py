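"""Published benchmark score tables and cross-dataset comparison helpers.

Ships the published ARI / purity / FMS tables of six spatial-clustering
tools (ADEPT, STAGATE, CCST, SEDR, SpaGCN, BayesSpace) on ten annotated
benchmark datasets — eight human cortex sections, one breast-cancer
section, one STARmap mouse cortex slice — so the ranking analysis can be
reproduced without any download.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .clustering import ScoreTable, rank_methods

__all__ = [
    "load_benchmark_table",
    "best_method_per_dataset",
    "count_best",
    "head_to_head",
    "average_rankings",
]


def load_benchmark_table(metric: str = "ari") -> ScoreTable:
    """Load the shipped 6-methods x 10-datasets table for a metric
    (``"ari"``, ``"purity"`` or ``"fms"``)."""
    metric = metric.lower()
    if metric not in {"ari", "purity", "fms"}:
        raise ValueError(f"unknown benchmark metric {metric!r}")
    with resources.files("adept").joinpath(f"data/benchmark_{metric}.csv").open() as fh:
        tab = pd.read_csv(fh, index_col=0)
    return ScoreTable(list(tab.index), list(tab.columns), tab.to_numpy())


def best_method_per_dataset(t: ScoreTable) -> pd.Series:
    """Method with the highest score in each dataset column."""
    frame = t.to_frame()
    return frame.idxmax(axis=0)


def count_best(t: ScoreTable, method: str) -> int:
    """Number of datasets on which ``method`` has the top score."""
    if method not in t.methods:
        raise KeyError(method)
    return int((best_method_per_dataset(t) == method).sum())


def head_to_head(t: ScoreTable, method_a: str, method_b: str, datasets=None) -> int:
    """Number of (selected) datasets where ``method_a`` beats ``method_b``."""
    frame = t.to_frame()
    if datasets is not None:
        frame = frame[list(datasets)]
    return int((frame.loc[method_a] > frame.loc[method_b]).sum())


def average_rankings(metric: str = "ari") -> pd.Series:
    """Average per-dataset rank of each method on the shipped table."""
    ranked = rank_methods(load_benchmark_table(metric))
    return ranked["avg_rank"]
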