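"""Per-gene two-group differential statistics.

Four scores are provided, each signed as (group 1 minus group 2):

- ``mod_t``   — moderated t with empirical-Bayes variance shrinkage,
- ``snr``     — signal-to-noise ratio (mean difference over the sum of the
  group standard deviations),
- ``ranksum`` — zero-centered Wilcoxon rank sum,
- ``logfc``   — log2 fold change of group means with a low-count offset.

All are computed on the normalized count scale.  The absolute transform
used by the one-tailed absolute enrichment test is :func:`absolute`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GeneScoreVector",
    "compute_scores",
    "moderated_t",
    "snr",
    "ranksum_zero_centered",
    "log_fold_change",
    "absolute",
    "squeeze_variance",
    "STATISTICS",
]

STATISTICS = ("mod_t", "snr", "ranksum", "logfc")


@dataclass
class GeneScoreVector:
    """Per-gene differential scores plus the group summaries they came from."""

    scores: pd.Series
    statistic: str
    mu1: pd.Series | None = None
    mu2: pd.Series | None = None
    sd1: pd.Series | None = None
    sd2: pd.Series | None = None
    is_absolute: bool = False

    def __len__(self) -> int:
        return self.scores.size


def _split(values: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    groups = np.asarray(list(groups))
    if groups.size != values.shape[1]:
        raise ValueError("one group label per sample column is required")
    levels = pd.unique(groups)
    if levels.size != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    mat = values.to_numpy(dtype=float)
    return mat, groups == levels[0], groups == levels[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by bracketed root-finding."""
    if y <= 0:
        return np.inf
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-10, 1e10
    return float(optimize.brentq(f, lo, hi, xtol=1e-8, rtol=1e-12))


def squeeze_variance(s2: np.ndarray, df: float, d0: float | None = None):
    """Empirical-Bayes shrinkage of per-gene sample variances.

    The marginal distribution of a scaled chi-square variance with a
    scaled-inverse-chi-square prior makes ``log s^2`` a shifted log-F; the
    prior degrees of freedom ``d0`` and prior variance ``s0^2`` are
    recovered by moment-matching the mean and variance of ``log s^2``
    across genes (digamma/trigamma inversion).  Genes with zero sample
    variance are excluded from the moment fit but still receive the
    posterior (squeezed) variance

        s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df).

    ``d0`` may be forced (0 recovers the raw variances; ``inf`` collapses
    every gene to ``s0^2``).  Returns ``(posterior s2, d0, s0_sq)``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("all gene variances are zero; cannot fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if d0 is None:
        if e.size < 2:  # no spread information: collapse to the prior
            e_var = -np.inf
        else:
            e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
        d0 = 2.0 * _trigamma_inverse(e_var) if e_var > 0 else np.inf
    if np.isinf(d0):
        s0_sq = float(np.exp(e_mean))
        return np.full_like(s2, s0_sq), d0, s0_sq
    if d0 == 0:
        s0_sq = float(np.exp(e_mean))
        return s2.copy(), d0, s0_sq
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


def moderated_t(values: pd.DataFrame, groups, d0: float | None = None) -> GeneScoreVector:
    """Moderated t-statistic: mean difference over the shrunken standard
    error, robust for very small replicate numbers.

    ``d0`` overrides the estimated prior degrees of freedom (``0`` gives
    the textbook pooled-variance two-sample t).
    """
    mat, g1, g2 = _split(values, groups)
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated t needs at least two replicates per group")
    m1, m2 = mat[:, g1].mean(axis=1), mat[:, g2].mean(axis=1)
    v1 = mat[:, g1].var(axis=1, ddof=1)
    v2 = mat[:, g2].var(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    post, d0_hat, _ = squeeze_variance(pooled, df, d0=d0)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    # a gene constant in both groups under d0=0 has zero posterior variance;
    # its mean difference is then also 0 — score it 0, not NaN
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    idx = values.index
    return GeneScoreVector(
        scores=pd.Series(t, index=idx, name="mod_t"),
        statistic="mod_t",
        mu1=pd.Series(m1, index=idx),
        mu2=pd.Series(m2, index=idx),
        sd1=pd.Series(np.sqrt(v1), index=idx),
        sd2=pd.Series(np.sqrt(v2), index=idx),
    )


def snr(values: pd.DataFrame, groups, sd_floor_frac: float = 0.2) -> GeneScoreVector:
    """Signal-to-noise ratio (mu1 - mu2) / (sd1 + sd2).

    Each group standard deviation is floored at
    ``max(sd_floor_frac * |group mean|, 1e-8)`` so genes with (near-)zero
    within-group variance get a finite score — the convention of the
    original GSEA implementation.
    """
    mat, g1, g2 = _split(values, groups)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("SNR needs at least two replicates per group")
    m1, m2 = mat[:, g1].mean(axis=1), mat[:, g2].mean(axis=1)
    s1 = mat[:, g1].std(axis=1, ddof=1)
    s2 = mat[:, g2].std(axis=1, ddof=1)
    f1 = np.maximum(s1, np.maximum(sd_floor_frac * np.abs(m1), 1e-8))
    f2 = np.maximum(s2, np.maximum(sd_floor_frac * np.abs(m2), 1e-8))
    score = (m1 - m2) / (f1 + f2)
    idx = values.index
    return GeneScoreVector(
        scores=pd.Series(score, index=idx, name="snr"),
        statistic="snr",
        mu1=pd.Series(m1, index=idx),
        mu2=pd.Series(m2, index=idx),
        sd1=pd.Series(s1, index=idx),
        sd2=pd.Series(s2, index=idx),
    )


def ranksum_zero_centered(values: pd.DataFrame, groups) -> GeneScoreVector:
    """Zero-centered Wilcoxon rank sum: per gene, the sum of the first
    group's within-gene sample ranks minus its null expectation
    ``n1 (n + 1) / 2``.  Midranks are used for ties, so the expectation
    under exchangeability is exactly zero."""
    mat, g1, g2 = _split(values, groups)
    n = mat.shape[1]
    n1 = int(g1.sum())
    if n < 4:
        raise ValueError("rank sum needs at least four samples in total")
    ranks = stats.rankdata(mat, axis=1)
    score = ranks[:, g1].sum(axis=1) - n1 * (n + 1) / 2.0
    idx = values.index
    mat1, mat2 = mat[:, g1], mat[:, g2]
    return GeneScoreVector(
        scores=pd.Series(score, index=idx, name="ranksum"),
        statistic="ranksum",
        mu1=pd.Series(mat1.mean(axis=1), index=idx),
        mu2=pd.Series(mat2.mean(axis=1), index=idx),
        sd1=pd.Series(mat1.std(axis=1, ddof=1), index=idx),
        sd2=pd.Series(mat2.std(axis=1, ddof=1), index=idx),
    )


def log_fold_change(values: pd.DataFrame, groups, offset: float = 0.0) -> GeneScoreVector:
    """log2((mu1 + offset) / (mu2 + offset)); the offset (typically the
    pooled 5th-percentile of nonzero normalized counts) keeps low-count
    genes from dominating."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    mat, g1, g2 = _split(values, groups)
    m1, m2 = mat[:, g1].mean(axis=1), mat[:, g2].mean(axis=1)
    if offset == 0 and ((m1 == 0) | (m2 == 0)).any():
        raise ValueError("zero group mean with zero offset; supply an offset")
    score = np.log2((m1 + offset) / (m2 + offset))
    idx = values.index
    return GeneScoreVector(
        scores=pd.Series(score, index=idx, name="logfc"),
        statistic="logfc",
        mu1=pd.Series(m1, index=idx),
        mu2=pd.Series(m2, index=idx),
        sd1=pd.Series(mat[:, g1].std(axis=1, ddof=1), index=idx),
        sd2=pd.Series(mat[:, g2].std(axis=1, ddof=1), index=idx),
    )


def absolute(vector: GeneScoreVector) -> GeneScoreVector:
    """Element-wise absolute transform |r| of a score vector."""
    return replace(
        vector,
        scores=vector.scores.abs(),
        is_absolute=True,
    )


def compute_scores(
    values: pd.DataFrame, groups, statistic: str, offset: float = 0.0, **kwargs
) -> GeneScoreVector:
    """Dispatch to one of the four statistics by name."""
    if statistic == "mod_t":
        return moderated_t(values, groups, **kwargs)
    if statistic == "snr":
        return snr(values, groups, **kwargs)
    if statistic == "ranksum":
        return ranksum_zero_centered(values, groups)
    if statistic == "logfc":
        return log_fold_change(values, groups, offset=offset)
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
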