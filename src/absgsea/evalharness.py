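"""Benchmark harness and gene-set diagnostics.

Reproduces the simulation benchmark — false-positive rate, power and AUC
of gene-permuting GSEA variants across within-set correlation levels and
replicate sizes — and provides the variance-inflation factor (VIF) and the
literature-relevance score used to characterize significant sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import countsim, gsea

__all__ = [
    "BenchmarkResult",
    "vif",
    "mean_intergene_correlation",
    "literature_score",
    "auc_from_qvalues",
    "make_gsea_runner",
    "benchmark",
]


def vif(k: int, rho_bar: float) -> float:
    """Variance inflation factor 1 + (K - 1) * rho_bar of a size-K
    competitive gene-set statistic with mean pairwise correlation rho_bar.

    A set of independent genes has VIF 1; positive correlation inflates
    the variance of the set statistic linearly in both K and rho_bar,
    which is what breaks the gene-permutation null.
    """
    if k < 1:
        raise ValueError("set size must be at least 1")
    if k == 1:
        return 1.0
    bound = -1.0 / (k - 1)
    if rho_bar < bound:
        raise ValueError(
            f"rho_bar {rho_bar:.4f} below the feasibility bound {bound:.4f} for K={k}"
        )
    return 1.0 + (k - 1) * rho_bar


def mean_intergene_correlation(values, gene_set) -> float:
    """Mean pairwise Pearson correlation among a set's member gene rows of
    an expression matrix (DataFrame indexed by gene)."""
    members = [g for g in gene_set if g in values.index]
    if len(members) < 2:
        raise ValueError("need at least two member genes present in the data")
    if values.shape[1] < 3:
        raise ValueError("need at least three samples to estimate correlations")
    return countsim.measure_mean_correlation(values.loc[members].to_numpy(float))


def literature_score(abstract_counts) -> float:
    """Log geometric average of per-gene abstract counts for a gene-set:
    mean over member genes of log(A_i), natural log.  Genes with zero
    abstracts contribute log(0 + 1) = 0 rather than -inf."""
    counts = np.asarray(list(abstract_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty gene-set")
    if (counts < 0).any():
        raise ValueError("abstract counts must be nonnegative")
    return float(np.mean(np.log(np.maximum(counts, 1.0))))


def auc_from_qvalues(qvalues: pd.Series, nes: pd.Series | None, truth_positive) -> float:
    """ROC AUC with sets ranked by ascending q-value, ties broken by
    descending |NES|, computed via the Mann-Whitney identity."""
    q = qvalues.fillna(1.0)
    if nes is None:
        key = pd.DataFrame({"q": q})
    else:
        key = pd.DataFrame({"q": q, "t": -nes.abs().fillna(0.0).reindex(q.index)})
    # encode the lexicographic (q asc, |NES| desc) order as a single score;
    # equal pairs share a code so AUC treats them as exact ties
    codes = pd.MultiIndex.from_frame(key).factorize(sort=True)[0]
    y = q.index.isin(set(truth_positive)).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AUC needs both positive and negative sets")
    return float(roc_auc_score(y, -codes.astype(float)))


def make_gsea_runner(
    statistic: str = "mod_t",
    mode: str = "standard",
    n_perm: int = 1000,
    normalize: bool = True,
    min_size: int = 10,
    max_size: int = 300,
):
    """Factory for benchmark method callables.

    The returned runner maps ``(counts, groups, gene_sets, seed)`` to a
    DataFrame indexed by set with columns ``q`` (the q-values significance
    is called on) and ``nes``.
    """

    def runner(counts, groups, gene_sets, seed):
        res = gsea.run_gsea(
            counts,
            groups,
            gene_sets,
            statistic=statistic,
            mode=mode,
            n_perm=n_perm,
            seed=seed,
            normalize=normalize,
            min_size=min_size,
            max_size=max_size,
        )
        tab = res.results.set_index("set")
        return pd.DataFrame({"q": res.qvalues, "nes": tab["nes"]})

    runner.__name__ = f"gsea_{mode}_{statistic}"
    return runner


@dataclass
class BenchmarkResult:
    """Per-repetition and aggregated benchmark metrics.

    ``per_repetition`` rows: method, repetition, fpr, tpr, auc (NaN where
    undefined, e.g. no DE sets for TPR/AUC, or a failed method run).
    ``aggregate`` averages the metrics over repetitions per method.
    """

    per_repetition: pd.DataFrame
    aggregate: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.aggregate = (
            self.per_repetition.groupby("method", sort=False)[["fpr", "tpr", "auc"]]
            .mean()
            .reset_index()
        )


def benchmark(
    methods: dict,
    n_repetitions: int = 5,
    seed=None,
    fdr: float = 0.1,
    sim_kwargs: dict | None = None,
) -> BenchmarkResult:
    """Run registered methods on freshly simulated studies and score them
    against the simulation truth.

    For each repetition a study is simulated (``sim_kwargs`` forwarded to
    :func:`absgsea.countsim.simulate_study`), every method is applied, and
    FPR (fraction of truth-negative sets called at q < ``fdr``), TPR
    (fraction of truth-positive sets called) and AUC (rank by q then
    |NES|) are recorded.  A method failure on a repetition is warned about
    and recorded as NaN, not propagated.
    """
    sim_kwargs = dict(sim_kwargs or {})
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep in range(n_repetitions):
        rep_seed, *method_seeds = [
            int(s) for s in (ss.spawn(1)[0].generate_state(1 + len(methods)) >> np.uint32(1))
        ]
        study = countsim.simulate_study(seed=rep_seed, **sim_kwargs)
        de = set(study.truth.de_sets)
        null = set(study.truth.null_sets)
        for (name, method), mseed in zip(methods.items(), method_seeds):
            try:
                out = method(study.counts, study.groups, study.gene_sets, mseed)
            except Exception as exc:  # noqa: BLE001 - benchmark must survive
                warnings.warn(f"method {name!r} failed on repetition {rep}: {exc}", stacklevel=2)
                rows.append({"method": name, "repetition": rep, "fpr": np.nan, "tpr": np.nan, "auc": np.nan})
                continue
            called = set(out.index[out["q"].fillna(1.0) < fdr])
            fpr = len(called & null) / len(null) if null else np.nan
            tpr = len(called & de) / len(de) if de else np.nan
            if de and null:
                auc = auc_from_qvalues(out["q"], out.get("nes"), de)
            else:
                auc = np.nan
            rows.append(
                {"method": name, "repetition": rep, "fpr": fpr, "tpr": tpr, "auc": auc}
            )
    return BenchmarkResult(pd.DataFrame(rows))
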