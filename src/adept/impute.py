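"""Dropout imputation by within-cluster gene means, averaged over DEG lists.

A dropout is an exactly-zero entry.  Given a clustering, each zero entry of
a gene is replaced by the mean of that gene's *non-zero* values over the
spots of the same cluster; if the gene is zero across the whole cluster the
entry stays zero.  Observed (non-zero) entries are never touched.

When several DEG lists (and hence several clusterings C_1..C_K) are in
play, each list's restricted matrix is imputed under its own clustering and
the results are averaged per entry over the lists that actually contain the
gene; the final matrix covers the union of all lists' genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterAssignment
from .dataset import NormalizedMatrix

__all__ = ["ImputationResult", "impute_with_clusters", "merge_imputations"]


def impute_with_clusters(x: NormalizedMatrix, c: ClusterAssignment) -> NormalizedMatrix:
    """Replace each zero entry by its gene's within-cluster non-zero mean."""
    values = x.values
    labels = np.asarray(c.labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("cluster labels must cover all spots")
    out = values.copy()
    for cl in np.unique(labels):
        rows = labels == cl
        block = values[rows]
        nz = block != 0
        support = nz.sum(axis=0)  # spots with a value, per gene
        with np.errstate(invalid="ignore"):
            mean = np.where(support > 0, block.sum(axis=0) / np.maximum(support, 1), 0.0)
        fill = np.broadcast_to(mean, block.shape)
        out[rows] = np.where(nz, block, fill)
    return NormalizedMatrix(
        values=out,
        gene_ids=list(x.gene_ids),
        spot_ids=list(x.spot_ids),
        provenance={**x.provenance, "imputed": True},
    )


@dataclass
class ImputationResult:
    """K per-list imputed matrices and their average over the gene union.

    ``final`` restricted to originally observed entries equals the input
    exactly; each imputed entry is the mean of the per-list estimates over
    the lists containing that gene.
    """

    per_list: list[NormalizedMatrix]
    final: NormalizedMatrix
    gene_union: list[str]
    observed_mask: np.ndarray  # True where the input was non-zero


def merge_imputations(
    per_list: list[NormalizedMatrix], original: NormalizedMatrix | None = None
) -> ImputationResult:
    """Average K imputed matrices over the union of their gene lists.

    The divisor for a gene is the number of lists containing it (not K), so
    genes present in only some lists are not shrunk toward zero.  When the
    pre-imputation matrix ``original`` is supplied the observed (non-zero)
    mask is cut from it; otherwise the mask is left all-False.
    """
    if not per_list:
        raise ValueError("need at least one imputed matrix")
    spot_ids = per_list[0].spot_ids
    for m in per_list[1:]:
        if m.spot_ids != spot_ids:
            raise ValueError("imputed matrices must share the same spots")
    union: list[str] = []
    seen = set()
    for m in per_list:
        for g in m.gene_ids:
            if g not in seen:
                seen.add(g)
                union.append(g)
    if not union:
        raise ValueError("empty gene union")
    n = len(spot_ids)
    total = np.zeros((n, len(union)))
    count = np.zeros(len(union))
    pos = {g: j for j, g in enumerate(union)}
    for m in per_list:
        cols = [pos[g] for g in m.gene_ids]
        total[:, cols] += m.values
        count[cols] += 1
    final_values = total / count
    observed = np.zeros((n, len(union)), dtype=bool)
    if original is not None:
        observed = original.restrict_genes(union).values != 0
        # observed entries are untouched by every list, so averaging must
        # return them exactly; enforce bit-identity against rounding
        final_values[observed] = original.restrict_genes(union).values[observed]
    final = NormalizedMatrix(
        values=final_values,
        gene_ids=union,
        spot_ids=list(spot_ids),
        provenance={"merged_lists": len(per_list)},
    )
    return ImputationResult(
        per_list=per_list,
        final=final,
        gene_union=union,
        observed_mask=observed,
    )
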