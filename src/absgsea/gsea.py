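"""Gene-permuting GSEA: weighted Kolmogorov-Smirnov enrichment scores,
permutation null, NES/FDR, the one-tailed absolute variant and the
false-positive filter that intersects both analyses.

The public surface is the :class:`GseaGenePermutation` model (construct
from a count matrix, group labels and gene-sets; ``fit`` runs the
permutation analysis and returns :class:`GseaResults`) plus the low-level
operations it composes, which are importable on their own.

Enrichment score
----------------
Genes are ranked by decreasing score ``r``.  Walking down the ranking, a
member gene ("hit") advances the running statistic by ``|r|^q / N_R``
(``N_R`` = total member weight) and a non-member ("miss") retreats it by
``1 / (N - N_H)``.  The standard (two-tailed) ES is the maximum deviation
from zero of either sign; the one-tailed absolute ES, computed on
absolute-valued scores, keeps only the positive maximum — so no set can
be called "down-regulated" and every permuted set contributes its positive
deviation to the null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import normalize as _norm
from . import scores as _scores
from .genesets import GeneSetCollection

__all__ = [
    "RankedList",
    "GseaResults",
    "GseaGenePermutation",
    "rank_genes",
    "enrichment_score",
    "gene_permutation_null",
    "normalize_and_fdr",
    "absolute_filter",
    "run_gsea",
]

MODES = ("standard", "absolute", "filtered")


@dataclass
class RankedList:
    """Genes ordered by decreasing score (ties broken by gene identifier)
    with the weights ``|r|^q`` used for the hit increments."""

    genes: np.ndarray
    scores: np.ndarray
    q: float = 1.0
    weights: np.ndarray = field(init=False)
    _pos: "pd.Index" = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.abs(self.scores) ** self.q if self.q != 0 else np.ones_like(self.scores)
        self._pos = pd.Index(self.genes)

    def __len__(self) -> int:
        return self.genes.size

    def positions(self, members) -> np.ndarray:
        """Sorted rank positions of the member genes; raises if any member
        is absent from the ranking."""
        idx = self._pos.get_indexer(list(members))
        if (idx < 0).any():
            missing = [m for m, i in zip(members, idx) if i < 0]
            raise KeyError(f"genes not in the ranked list: {missing[:5]}")
        idx.sort()
        return idx


def rank_genes(score_vector, q: float = 1.0) -> RankedList:
    """Build the ranked list from a :class:`~absgsea.scores.GeneScoreVector`
    or a pandas Series, sorting by score descending with deterministic
    gene-identifier tie-breaking."""
    series = getattr(score_vector, "scores", score_vector)
    # stable sort on gene id first, then score, gives (score desc, gene asc)
    order = series.sort_index().sort_values(ascending=False, kind="mergesort")
    return RankedList(order.index.to_numpy(), order.to_numpy(dtype=float), q=q)


# ---------------------------------------------------------------------------
# enrichment-score computation


def _es_batch(pos: np.ndarray, weights: np.ndarray, n_genes: int, one_tailed: bool) -> np.ndarray:
    """ES for many same-size sets given their sorted rank positions.

    ``pos`` is (n_sets, K).  Exploits that the running statistic attains
    local maxima only immediately after a hit and local minima only
    immediately before one, so each set costs O(K) instead of O(N).
    """
    m, k = pos.shape
    if k >= n_genes:
        raise ValueError("a gene-set must be strictly smaller than the ranked list")
    w = weights[pos]
    nr = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        hit = np.where(nr > 0, np.cumsum(w, axis=1) / nr, 0.0)
    j = np.arange(k)
    miss = (pos - j) / (n_genes - k)  # misses seen before/at each hit
    dev_after = hit - miss
    max_dev = dev_after.max(axis=1)
    if one_tailed:
        return max_dev
    hit_before = np.concatenate([np.zeros((m, 1)), hit[:, :-1]], axis=1)
    min_dev = (hit_before - miss).min(axis=1)
    return np.where(np.abs(max_dev) >= np.abs(min_dev), max_dev, min_dev)


def enrichment_score(ranked: RankedList, members, one_tailed: bool = False):
    """ES of one gene-set with the full running profile and leading edge.

    Returns ``(es, running, leading_edge)`` where ``running`` has one value
    per ranked gene and ``leading_edge`` lists the member genes appearing
    up to (positive ES) or from (negative ES) the extremum.
    """
    members = list(members)
    n = len(ranked)
    if not members:
        raise ValueError("empty gene-set")
    pos = ranked.positions(members)
    k = pos.size
    if k >= n:
        raise ValueError("gene-set must be strictly smaller than the ranked list")
    nr = ranked.weights[pos].sum()
    if nr == 0:
        raise ValueError(
            "all member gene scores are zero (N_R = 0); enrichment undefined "
            f"for this {k}-gene set"
        )
    steps = np.full(n, -1.0 / (n - k))
    steps[pos] = ranked.weights[pos] / nr
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    es_max = running[i_max]
    if one_tailed:
        es, extremum, positive = es_max, i_max, True
    else:
        i_min = int(np.argmin(running))
        es_min = running[i_min]
        if abs(es_max) >= abs(es_min):
            es, extremum, positive = es_max, i_max, True
        else:
            es, extremum, positive = es_min, i_min, False
    if positive:
        lead = pos[pos <= extremum]
    else:
        lead = pos[pos >= extremum]
    leading_edge = list(ranked.genes[lead])
    return float(es), running, leading_edge


def _sample_positions(n_genes: int, k: int, n_perm: int, rng, chunk: int = 256):
    """Yield (rows, K) arrays of sorted random K-subsets of range(n_genes)."""
    done = 0
    while done < n_perm:
        rows = min(chunk, n_perm - done)
        u = rng.random((rows, n_genes))
        pos = np.argpartition(u, k, axis=1)[:, :k]
        pos.sort(axis=1)
        yield pos
        done += rows


def gene_permutation_null(
    ranked: RankedList,
    set_sizes,
    n_perm: int = 1000,
    seed=None,
    one_tailed: bool = False,
    exhaustive_limit: int = 10_000,
) -> dict[int, np.ndarray]:
    """Null ES ensembles from gene permutation, one per distinct set size.

    Permuting gene labels is equivalent to scoring random same-size
    subsets of the ranked list, so one ensemble is shared by all sets of
    equal size.  When the number of possible subsets ``C(N, K)`` does not
    exceed ``exhaustive_limit`` the null is enumerated exactly instead of
    sampled.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    out: dict[int, np.ndarray] = {}
    for k in sorted(set(int(s) for s in set_sizes)):
        if math.comb(n, k) <= exhaustive_limit:
            pos = np.array(list(itertools.combinations(range(n), k)), dtype=np.int64)
            out[k] = _es_batch(pos, ranked.weights, n, one_tailed)
        else:
            parts = [
                _es_batch(pos, ranked.weights, n, one_tailed)
                for pos in _sample_positions(n, k, n_perm, rng)
            ]
            out[k] = np.concatenate(parts)
    return out


# ---------------------------------------------------------------------------
# NES, p-values, FDR


def _side_counts(arr: np.ndarray, value: float) -> tuple[int, int]:
    if value >= 0:
        side = arr[arr >= 0]
        return int((side >= value).sum()), side.size
    side = arr[arr < 0]
    return int((side <= value).sum()), side.size


def normalize_and_fdr(observed: pd.DataFrame, nulls: dict[int, np.ndarray], mode: str) -> pd.DataFrame:
    """Normalize observed and null enrichment scores and attach nominal
    p-values and permutation-based FDR q-values.

    NES divides each ES by the mean same-sign null ES of its set size
    (positive and negative sides separately in standard mode; the single
    nonnegative side in absolute mode).  The nominal p-value is the
    add-one-smoothed fraction of same-sign nulls at least as extreme.  The
    FDR for a set at NES* is the ratio of the pooled-null tail fraction to
    the observed tail fraction beyond NES*, clipped to [0, 1] and made
    monotone nonincreasing in |NES| within each sign.
    """
    if mode not in ("standard", "absolute"):
        raise ValueError("mode must be 'standard' or 'absolute'")
    obs = observed.copy()
    pos_mean: dict[int, float] = {}
    neg_mean: dict[int, float] = {}
    null_nes_parts = []
    for k, arr in nulls.items():
        pos = arr[arr >= 0]
        neg = arr[arr < 0]
        pos_mean[k] = float(pos.mean()) if pos.size else np.nan
        neg_mean[k] = float(np.abs(neg).mean()) if neg.size else np.nan
        nes_k = np.empty_like(arr)
        if pos.size:
            nes_k[arr >= 0] = pos / pos_mean[k] if pos_mean[k] > 0 else 0.0
        if neg.size:
            nes_k[arr < 0] = neg / neg_mean[k]
        null_nes_parts.append(nes_k)
    null_nes = np.concatenate(null_nes_parts)

    nes = np.full(len(obs), np.nan)
    pval = np.full(len(obs), np.nan)
    for i, row in enumerate(obs.itertuples(index=False)):
        k, es = int(row.size), float(row.es)
        arr = nulls[k]
        if es >= 0:
            denom = pos_mean[k]
            if not np.isfinite(denom) or denom <= 0:
                warnings.warn(
                    f"no positive null ES for size {k}; NES undefined for "
                    f"set {row.set}",
                    stacklevel=2,
                )
                continue
            nes[i] = es / denom
        else:
            denom = neg_mean[k]
            if not np.isfinite(denom) or denom <= 0:
                warnings.warn(
                    f"no negative null ES for size {k}; NES undefined for "
                    f"set {row.set}",
                    stacklevel=2,
                )
                continue
            nes[i] = es / denom
        extreme, total = _side_counts(arr, es)
        pval[i] = (1.0 + extreme) / (1.0 + total)

    obs["nes"] = nes
    obs["pval"] = pval

    q = np.full(len(obs), np.nan)
    obs_nes = nes
    n_null_pos = int((null_nes >= 0).sum())
    n_null_neg = int((null_nes < 0).sum())
    n_obs_pos = int((obs_nes >= 0).sum())
    n_obs_neg = int((obs_nes < 0).sum())
    for i, v in enumerate(obs_nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            if n_null_pos == 0 or n_obs_pos == 0:
                continue
            num = (null_nes >= v).sum() / n_null_pos
            den = (obs_nes >= v).sum() / n_obs_pos
        else:
            num = (null_nes <= v).sum() / n_null_neg if n_null_neg else np.nan
            den = (obs_nes <= v).sum() / n_obs_neg
        q[i] = min(1.0, num / den) if den > 0 else np.nan

    # monotone: a more extreme |NES| never has a larger q than a less
    # extreme one of the same sign (running minimum from the weak end)
    for sign_mask in (obs_nes >= 0, obs_nes < 0):
        idx = np.where(sign_mask & np.isfinite(q))[0]
        if idx.size == 0:
            continue
        order = idx[np.argsort(-np.abs(obs_nes[idx]), kind="mergesort")]
        q[order] = np.minimum.accumulate(q[order][::-1])[::-1]

    obs["fdr_q"] = q
    obs["direction"] = np.where(obs["es"] < 0, "down", "up")
    obs["mode"] = mode
    return obs


def absolute_filter(
    standard: pd.DataFrame,
    absolute: pd.DataFrame,
    fdr_standard: float = 0.1,
    fdr_absolute: float = 0.1,
) -> pd.DataFrame:
    """Intersect the standard and one-tailed absolute analyses.

    A set is significant only when its q-value passes ``fdr_standard`` in
    the standard run *and* ``fdr_absolute`` in the absolute run.  The
    returned table keeps every set with the standard run's statistics and
    direction, both q-values (``q_standard``, ``q_absolute``) and a
    ``significant`` flag.
    """
    if set(standard["set"]) != set(absolute["set"]):
        raise ValueError("standard and absolute results cover different gene-sets")
    merged = standard.rename(columns={"fdr_q": "q_standard"}).merge(
        absolute[["set", "fdr_q"]].rename(columns={"fdr_q": "q_absolute"}),
        on="set",
        validate="one_to_one",
    )
    merged["significant"] = (merged["q_standard"] < fdr_standard) & (
        merged["q_absolute"] < fdr_absolute
    )
    merged["mode"] = "filtered"
    return merged


# ---------------------------------------------------------------------------
# model / results objects


class GseaResults:
    """Fitted gene-permuting GSEA results.

    Attributes
    ----------
    results : pandas.DataFrame
        One row per tested gene-set.  Columns always include ``set``,
        ``size``, ``es``, ``nes``, ``pval`` and ``direction``; standard and
        absolute runs carry ``fdr_q`` while filtered runs carry
        ``q_standard``, ``q_absolute`` and ``significant``.
    """

    def __init__(self, results, mode, statistic, n_perm, seed, fdr, fdr_absolute, offset=None, size_factors=None, model=None):
        self.results = results.reset_index(drop=True)
        self.mode = mode
        self.statistic = statistic
        self.n_perm = n_perm
        self.seed = seed
        self.fdr = fdr
        self.fdr_absolute = fdr_absolute
        self.offset = offset
        self.size_factors = size_factors
        self.model = model

    def significant(self, fdr: float | None = None, fdr_absolute: float | None = None) -> pd.DataFrame:
        """Significant sets at the given cutoffs (defaults: the fit's)."""
        fdr = self.fdr if fdr is None else fdr
        if self.mode == "filtered":
            fdr_absolute = (
                (self.fdr_absolute if self.fdr_absolute is not None else fdr)
                if fdr_absolute is None
                else fdr_absolute
            )
            mask = (self.results["q_standard"] < fdr) & (
                self.results["q_absolute"] < fdr_absolute
            )
        else:
            mask = self.results["fdr_q"] < fdr
        return self.results[mask.fillna(False)]

    @property
    def qvalues(self) -> pd.Series:
        """Per-set q-values used for significance calls, indexed by set.

        For filtered mode this is the elementwise maximum of the standard
        and absolute q-values — a set is significant at cutoff c exactly
        when this value is below c (with equal cutoffs on both runs).
        """
        r = self.results.set_index("set")
        if self.mode == "filtered":
            return r[["q_standard", "q_absolute"]].max(axis=1)
        return r["fdr_q"]

    def summary(self, max_rows: int = 20) -> str:
        sig = self.significant()
        lines = [
            "Gene-permuting GSEA results",
            "===========================",
            f"mode:           {self.mode}",
            f"gene statistic: {self.statistic}",
            f"gene-sets:      {len(self.results)}",
            f"permutations:   {self.n_perm}   seed: {self.seed}",
            f"FDR cutoff:     {self.fdr}"
            + (f" (absolute: {self.fdr_absolute})" if self.mode == "filtered" else ""),
            f"significant:    {len(sig)}",
            "",
        ]
        cols = [c for c in ("set", "size", "es", "nes", "pval", "fdr_q", "q_standard", "q_absolute", "direction") if c in self.results.columns]
        by = "q_standard" if self.mode == "filtered" else "fdr_q"
        table = self.results.sort_values(by).head(max_rows)[cols]
        lines.append(table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<GseaResults mode={self.mode} statistic={self.statistic} "
            f"sets={len(self.results)} significant={len(self.significant())}>"
        )

    def to_tsv(self, path) -> None:
        from .io import write_results

        write_results(self, path)


class GseaGenePermutation:
    """Gene-permuting GSEA model for a two-group count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Genes x samples matrix; raw counts unless ``normalize=False``.
    groups : sequence of str
        Group label per sample column (exactly two distinct labels; the
        first label encountered is group 1, the score numerator).
    gene_sets : mapping or GeneSetCollection
        Set name -> member gene identifiers.
    statistic : {"mod_t", "snr", "ranksum", "logfc"}
        Per-gene differential score.
    mode : {"standard", "absolute", "filtered"}
        ``standard`` is the ordinary signed two-tailed test; ``absolute``
        ranks absolute-valued scores and keeps only the positive (right
        tail) deviation; ``filtered`` runs both on the same score vector
        and intersects their significant sets.
    q_weight : float
        Weighting exponent on |score| in the running statistic (1.0 as
        recommended; 0 gives the classical unweighted K-S statistic).
    normalize : bool
        Apply median-of-ratios normalization (disable for pre-normalized
        input).
    min_size, max_size : int
        Inclusive bounds on effective gene-set size after intersecting
        with the data.
    two_tailed_absolute : bool
        Use the two-tailed ES on absolute scores instead of the one-tailed
        variant (for comparison experiments).

    Examples
    --------
    >>> model = GseaGenePermutation(counts, groups, sets, statistic="mod_t",
    ...                             mode="filtered")
    >>> res = model.fit(n_perm=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups,
        gene_sets,
        statistic: str = "mod_t",
        mode: str = "filtered",
        q_weight: float = 1.0,
        normalize: bool = True,
        min_size: int = 10,
        max_size: int = 300,
        two_tailed_absolute: bool = False,
    ):
        if statistic not in _scores.STATISTICS:
            raise ValueError(f"statistic must be one of {_scores.STATISTICS}")
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.statistic = statistic
        self.mode = mode
        self.q_weight = q_weight
        self.two_tailed_absolute = two_tailed_absolute
        self.groups = list(groups)

        if normalize:
            nm = _norm.median_ratio_normalize(counts)
            self.values = nm.values
            self.size_factors = nm.size_factors
        else:
            self.values = counts.astype(float)
            self.size_factors = pd.Series(1.0, index=counts.columns, name="size_factor")
        self.offset = _norm.low_count_offset(self.values)
        if not isinstance(gene_sets, GeneSetCollection):
            gene_sets = GeneSetCollection(gene_sets)
        self.gene_sets = gene_sets.restrict(self.values.index, min_size, max_size)
        if len(self.gene_sets) == 0:
            raise ValueError("no gene-set left after restriction to the data")

    @classmethod
    def from_files(cls, counts_path, groups_path, gmt_path, **kwargs):
        from . import io as _io
        from .genesets import read_gmt

        counts = _io.read_counts(counts_path)
        design = _io.read_groups(groups_path)
        gene_sets = read_gmt(gmt_path)
        return cls(counts, design.labels_for(counts.columns), gene_sets, **kwargs)

    # -- internals ---------------------------------------------------------

    def _score_vector(self):
        return _scores.compute_scores(
            self.values, self.groups, self.statistic, offset=self.offset
        )

    def _single_mode(self, score_vector, one_tailed, mode_label, n_perm, seed, exhaustive_limit):
        ranked = rank_genes(score_vector, q=self.q_weight)
        rows = []
        for name, members in self.gene_sets.items():
            es, _, lead = enrichment_score(ranked, members, one_tailed=one_tailed)
            rows.append(
                {"set": name, "size": len(members), "es": es, "leading_edge": ",".join(lead)}
            )
        observed = pd.DataFrame(rows)
        nulls = gene_permutation_null(
            ranked,
            observed["size"],
            n_perm=n_perm,
            seed=seed,
            one_tailed=one_tailed,
            exhaustive_limit=exhaustive_limit,
        )
        return normalize_and_fdr(observed, nulls, mode_label)

    def fit(
        self,
        n_perm: int = 1000,
        seed=None,
        fdr: float = 0.1,
        fdr_absolute: float | None = None,
        exhaustive_limit: int = 10_000,
    ) -> GseaResults:
        """Run the permutation analysis.

        ``fdr``/``fdr_absolute`` are the significance cutoffs recorded on
        the results (``fdr_absolute`` defaults to ``fdr``; it only matters
        in filtered mode).
        """
        ss = np.random.SeedSequence(seed)
        seed_std, seed_abs = ss.generate_state(2) >> np.uint32(1)
        vector = self._score_vector()
        if self.mode == "standard":
            table = self._single_mode(
                vector, False, "standard", n_perm, int(seed_std), exhaustive_limit
            )
        elif self.mode == "absolute":
            table = self._single_mode(
                _scores.absolute(vector),
                not self.two_tailed_absolute,
                "absolute",
                n_perm,
                int(seed_abs),
                exhaustive_limit,
            )
        else:
            std = self._single_mode(
                vector, False, "standard", n_perm, int(seed_std), exhaustive_limit
            )
            ab = self._single_mode(
                _scores.absolute(vector),
                not self.two_tailed_absolute,
                "absolute",
                n_perm,
                int(seed_abs),
                exhaustive_limit,
            )
            table = absolute_filter(
                std, ab, fdr, fdr if fdr_absolute is None else fdr_absolute
            )
        return GseaResults(
            table,
            self.mode,
            self.statistic,
            n_perm,
            seed,
            fdr,
            fdr if fdr_absolute is None else fdr_absolute,
            offset=self.offset,
            size_factors=self.size_factors,
            model=self,
        )


def run_gsea(
    counts,
    groups,
    gene_sets,
    statistic: str = "mod_t",
    mode: str = "filtered",
    n_perm: int = 1000,
    fdr: float = 0.1,
    fdr_absolute: float | None = None,
    seed=None,
    **model_kwargs,
) -> GseaResults:
    """One-call pipeline: normalize, score, permute, filter."""
    model = GseaGenePermutation(
        counts, groups, gene_sets, statistic=statistic, mode=mode, **model_kwargs
    )
    return model.fit(n_perm=n_perm, seed=seed, fdr=fdr, fdr_absolute=fdr_absolute)
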