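"""Count normalization (median-of-ratios) and the low-count logFC offset."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalizedMatrix", "median_ratio_normalize", "low_count_offset", "restrict_gene_sets"]


@dataclass
class NormalizedMatrix:
    """Normalized genes x samples expression values.

    ``values`` are raw counts divided column-wise by ``size_factors``;
    ``offset`` is the pooled low-count offset (``None`` until computed by
    :func:`low_count_offset`).
    """

    values: pd.DataFrame
    size_factors: pd.Series
    offset: float | None = None


def median_ratio_normalize(raw: pd.DataFrame) -> NormalizedMatrix:
    """Median-of-ratios normalization.

    Each sample's size factor is the median, over genes expressed in every
    sample, of that sample's count divided by the gene's geometric mean
    across samples.  Genes with a zero anywhere are excluded from the
    reference, the standard convention for this estimator.
    """
    mat = raw.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "needs at least one such gene (consider filtering samples or "
            "using pre-normalized input)"
        )
    log_ref = np.log(mat[all_pos]).mean(axis=1)
    ratios = np.log(mat[all_pos]) - log_ref[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    values = raw.astype(float) / size_factors
    return NormalizedMatrix(
        values=values,
        size_factors=pd.Series(size_factors, index=raw.columns, name="size_factor"),
    )


def low_count_offset(norm: NormalizedMatrix | pd.DataFrame, q: float = 0.05) -> float:
    """Offset stabilizing the logFC of weakly expressed genes: the 5th
    percentile (linear-interpolation quantile) of the pooled nonzero
    normalized values."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    pool = np.asarray(values, dtype=float).ravel()
    pool = pool[pool > 0]
    if pool.size == 0:
        raise ValueError("all normalized values are zero; offset undefined")
    offset = float(np.quantile(pool, q))
    if isinstance(norm, NormalizedMatrix):
        norm.offset = offset
    return offset


def restrict_gene_sets(gene_sets, genes, min_size: int = 10, max_size: int = 300):
    """Intersect sets with the data's genes and apply the size filter
    (bounds inclusive).  Thin wrapper over
    :meth:`~absgsea.genesets.GeneSetCollection.restrict`."""
    from .genesets import GeneSetCollection

    if not isinstance(gene_sets, GeneSetCollection):
        gene_sets = GeneSetCollection(gene_sets)
    return gene_sets.restrict(genes, min_size=min_size, max_size=max_size)
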