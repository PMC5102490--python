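"""Simulation of RNA-seq read counts with within-gene-set correlation.

Counts are negative binomial (NB) with per-gene mean ``mu`` and dispersion
``phi`` (variance ``mu + phi*mu**2``; ``phi = 0`` is exact Poisson).
Correlation inside a gene-set is induced by mixing each gene's independent
count ``C`` with a "commonly generated" count ``C*`` obtained by pushing one
shared uniform variable per sample through each gene's NB quantile function:

    M = round((1 - alpha) * C + alpha * C*)

The mixture shrinks the marginal variance by ``2*alpha**2 - 2*alpha + 1``,
so both ``C`` and ``C*`` are drawn with an inflated dispersion ``phi'``
chosen to conserve the target variance (see :func:`inflate_dispersion`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NBParams",
    "CorrelationSpec",
    "DEInjectionSpec",
    "SimTruth",
    "SimulatedStudy",
    "CalibrationError",
    "inflate_dispersion",
    "simulate_independent_counts",
    "simulate_correlated_set",
    "measure_mean_correlation",
    "calibrate_alpha",
    "default_nb_params",
    "simulate_study",
]


class CalibrationError(RuntimeError):
    """Raised when no mixing coefficient reaches the requested correlation."""


@dataclass
class NBParams:
    """Per-gene negative-binomial parameters.

    Parameters
    ----------
    mu : array-like
        Per-gene expected counts, strictly positive.
    phi : array-like
        Per-gene dispersions, nonnegative.  The implied variance is
        ``mu + phi * mu**2``; ``phi == 0`` yields a Poisson gene.
    size_factors : array-like, optional
        Per-sample scaling constants (default: all ones).
    """

    mu: np.ndarray
    phi: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.mu.shape != self.phi.shape:
            raise ValueError("mu and phi must have equal length")
        if np.any(self.mu <= 0):
            raise ValueError("all NB means must be strictly positive")
        if np.any(self.phi < 0):
            raise ValueError("dispersions must be nonnegative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ValueError("size factors must be strictly positive")

    def __len__(self) -> int:
        return self.mu.size

    def subset(self, idx) -> "NBParams":
        return NBParams(self.mu[idx], self.phi[idx], self.size_factors)


@dataclass
class CorrelationSpec:
    """Within-set correlation request: a mixing coefficient and/or a target
    mean pairwise Pearson correlation (resolved by :func:`calibrate_alpha`)."""

    alpha: float | None = None
    target_rho: float | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.target_rho is not None and not 0.0 <= self.target_rho <= 1.0:
            raise ValueError("target_rho must lie in [0, 1]")
        if self.alpha is None and self.target_rho is None:
            raise ValueError("provide alpha or target_rho")


@dataclass
class DEInjectionSpec:
    """Differential-expression injection settings for :func:`simulate_study`.

    Defaults follow the benchmark design: 20% of gene-sets are made DE; in
    each DE set a uniformly random 20-80% of the genes get their mean in one
    group (test or control, chosen at random per gene) multiplied by a fold
    drawn uniformly from 1.5-2.0; DE sets receive only weak within-set
    correlation (mean pairwise rho in [0, 0.05]).
    """

    frac_de_sets: float = 0.2
    frac_de_genes_range: tuple[float, float] = (0.2, 0.8)
    fold_range: tuple[float, float] = (1.5, 2.0)
    de_set_rho_range: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de_sets <= 1.0:
            raise ValueError("frac_de_sets must lie in [0, 1]")
        lo, hi = self.frac_de_genes_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("frac_de_genes_range must be an interval in [0, 1]")
        flo, fhi = self.fold_range
        if not (flo > 1.0 and fhi >= flo):
            raise ValueError("fold_range lower bound must exceed 1")
        rlo, rhi = self.de_set_rho_range
        if not (0.0 <= rlo <= rhi <= 1.0):
            raise ValueError("de_set_rho_range must be an interval in [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth labels of a simulated study.

    ``set_table`` has one row per gene-set (columns: ``set``, ``is_de``,
    ``alpha``); ``gene_table`` one row per gene inside a set (columns:
    ``gene``, ``set``, ``is_de``, ``fold``, ``fold_group``).  Folds are
    recorded only for DE genes, and DE genes occur only inside DE sets.
    """

    set_table: pd.DataFrame
    gene_table: pd.DataFrame

    @property
    def de_sets(self) -> list[str]:
        tab = self.set_table
        return list(tab.loc[tab["is_de"], "set"])

    @property
    def null_sets(self) -> list[str]:
        tab = self.set_table
        return list(tab.loc[~tab["is_de"], "set"])


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`."""

    counts: pd.DataFrame
    groups: list[str]
    gene_sets: "dict[str, list[str]]"
    truth: SimTruth

    def __iter__(self):
        return iter((self.counts, self.groups, self.gene_sets, self.truth))


# ---------------------------------------------------------------------------
# sampling primitives


def inflate_dispersion(phi, mu, alpha):
    """Dispersion that conserves the NB variance under alpha-mixing.

    Solves ``(2a^2 - 2a + 1) * (mu + phi' mu^2) = mu + phi mu^2`` for
    ``phi'``, i.e. ``phi' = (1 + phi*mu) / (mu*(2a^2 - 2a + 1)) - 1/mu``.
    Returns ``phi`` unchanged at ``alpha`` 0 or 1 and is largest at 0.5.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    shrink = 2.0 * alpha * alpha - 2.0 * alpha + 1.0
    return (1.0 + phi * mu) / (mu * shrink) - 1.0 / mu


def _nb_rvs(mu, phi, shape, rng):
    """NB variates with mean ``mu`` and dispersion ``phi`` (size = 1/phi);
    exact Poisson where ``phi == 0``.  ``mu``/``phi`` broadcast to ``shape``."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), shape)
    out = np.empty(shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        size = 1.0 / phi[~pois]
        prob = size / (size + mu[~pois])
        out[~pois] = rng.negative_binomial(size, prob)
    return out


def _nb_ppf(p, mu, phi):
    """Discrete quantile: smallest integer c with ``CDF(c) >= p``."""
    p, mu, phi = np.broadcast_arrays(
        np.asarray(p, float), np.asarray(mu, float), np.asarray(phi, float)
    )
    out = np.empty(p.shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = stats.poisson.ppf(p[pois], mu[pois]).astype(np.int64)
    if np.any(~pois):
        size = 1.0 / phi[~pois]
        prob = size / (size + mu[~pois])
        out[~pois] = stats.nbinom.ppf(p[~pois], size, prob).astype(np.int64)
    return out


def simulate_independent_counts(params: NBParams, n_samples: int, seed=None) -> np.ndarray:
    """Genes x samples matrix of independent NB counts."""
    rng = np.random.default_rng(seed)
    k = len(params)
    mu = params.mu[:, None]
    if params.size_factors is not None:
        if params.size_factors.size != n_samples:
            raise ValueError("size_factors length must equal n_samples")
        mu = mu * params.size_factors[None, :]
    return _nb_rvs(mu, params.phi[:, None], (k, n_samples), rng)


def simulate_correlated_set(
    params: NBParams,
    n_samples: int,
    alpha: float,
    seed=None,
    mu_override: np.ndarray | None = None,
) -> np.ndarray:
    """Counts for one gene-set with within-set correlation controlled by
    ``alpha``.

    One uniform is drawn per sample and shared by every gene of the set;
    pushed through each gene's NB quantile function it yields the common
    count ``C*`` that is mixed with the independent count ``C``.  Both are
    generated with the variance-conserving inflated dispersion.

    ``mu_override`` (genes x samples), when given, replaces the per-gene
    mean cell-wise — used to apply group-specific fold changes.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = len(params)
    mu = np.broadcast_to(params.mu[:, None], (k, n_samples)).astype(float)
    if mu_override is not None:
        mu = np.asarray(mu_override, dtype=float)
        if mu.shape != (k, n_samples):
            raise ValueError("mu_override must be genes x samples")
    if params.size_factors is not None:
        mu = mu * params.size_factors[None, :]
    phi_infl = inflate_dispersion(params.phi, params.mu, alpha)[:, None]

    c_ind = _nb_rvs(mu, phi_infl, (k, n_samples), rng)
    if alpha == 0.0:
        return c_ind
    p_shared = rng.random(n_samples)
    c_common = _nb_ppf(p_shared[None, :], mu, phi_infl)
    mixed = (1.0 - alpha) * c_ind + alpha * c_common
    # round half to even: the mixture lives on a coarse lattice (multiples
    # of gcd(alpha, 1-alpha)), where always rounding .5 ties upward would
    # bias the marginal mean and break variance conservation
    return np.rint(mixed).astype(np.int64)


def measure_mean_correlation(matrix: np.ndarray) -> float:
    """Mean pairwise Pearson correlation of the rows; constant rows are
    excluded (with a warning) since their correlations are undefined."""
    matrix = np.asarray(matrix, dtype=float)
    keep = matrix.std(axis=1) > 0
    if keep.sum() < 2:
        raise ValueError("need at least two non-constant rows")
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant row(s) from correlation",
            stacklevel=2,
        )
    corr = np.corrcoef(matrix[keep])
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def calibrate_alpha(
    params: NBParams,
    target_rho: float,
    n_samples: int = 300,
    seed=None,
    tol: float = 0.02,
    max_iter: int = 40,
    n_probe: int = 3,
) -> float:
    """Find the mixing coefficient whose measured mean pairwise correlation
    matches ``target_rho`` within ``tol``.

    Each probe simulates ``n_probe`` independent matrices and averages
    their mean pairwise correlations, which damps the noise contributed by
    any single draw of the shared uniforms.  The empirical
    alpha-to-correlation curve is monotone; common random numbers (the
    same seeds at every probe) keep it monotone under sampling noise, so
    plain bisection converges.  Raises :class:`CalibrationError` when the
    target exceeds the correlation achievable at ``alpha = 1``.
    """
    if target_rho < 0:
        raise ValueError("target_rho must be nonnegative")
    if target_rho == 0:
        return 0.0
    probe_seeds = np.random.SeedSequence(seed).generate_state(n_probe)

    def measured(alpha: float) -> float:
        return float(
            np.mean(
                [
                    measure_mean_correlation(
                        simulate_correlated_set(params, n_samples, alpha, seed=s)
                    )
                    for s in probe_seeds
                ]
            )
        )

    hi_val = measured(1.0)
    if target_rho > hi_val + tol:
        raise CalibrationError(
            f"target correlation {target_rho:.3f} unreachable: alpha=1 "
            f"attains only {hi_val:.3f}"
        )
    lo, hi = 0.0, 1.0
    val = hi_val
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = measured(mid)
        if abs(val - target_rho) <= 0.5 * tol:
            return mid
        if val < target_rho:
            lo = mid
        else:
            hi = mid
    if abs(val - target_rho) > tol:
        raise CalibrationError(
            f"bisection did not reach {target_rho:.3f} (last measured {val:.3f})"
        )
    return 0.5 * (lo + hi)


def default_nb_params(n_genes: int, seed=None) -> NBParams:
    """Synthetic per-gene (mu, phi) table emulating a filtered bulk RNA-seq
    dataset.

    Means are log-normal (median ~150 counts) truncated below at 10 — the
    usual low-count filter — and dispersions are gamma with mean 0.3,
    spanning roughly 0.02-1, the range of tag-wise estimates typical for
    tumour cohorts.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(5.0, 1.0, n_genes))
    mu = np.clip(mu, 10.0, None)
    phi = rng.gamma(2.0, 0.15, n_genes)
    return NBParams(mu, phi)


def _partition_sets(n_genes: int, n_sets: int, set_size: int, rng) -> dict[str, np.ndarray]:
    """Non-overlapping sets assigned to a random subset of gene indices.

    Random (rather than contiguous) assignment mirrors real data, where
    gene identifiers carry no information about set membership; with
    heavily tied discrete scores a layout aligned with the identifier
    order would otherwise interact with deterministic tie-breaking."""
    if n_sets * set_size > n_genes:
        raise ValueError("gene-set layout exceeds the number of genes")
    width = max(3, len(str(n_sets)))
    perm = rng.permutation(n_genes)
    return {
        f"set_{s + 1:0{width}d}": np.sort(perm[s * set_size : (s + 1) * set_size])
        for s in range(n_sets)
    }


def simulate_study(
    n_genes: int = 10_000,
    n_sets: int = 100,
    set_size: int = 100,
    n1: int = 3,
    n2: int = 3,
    correlation: CorrelationSpec | float | None = None,
    de_spec: DEInjectionSpec | None = None,
    nb_params: NBParams | None = None,
    set_layout: dict[str, np.ndarray] | None = None,
    seed=None,
) -> SimulatedStudy:
    """Simulate a full two-group count study with gene-sets and truth labels.

    The default layout mirrors the benchmark design: 10,000 genes carved
    into 100 non-overlapping sets of 100 genes, two groups of ``n1``/``n2``
    replicates.  Non-DE sets receive the requested within-set correlation
    (``correlation`` is a :class:`CorrelationSpec`, a bare alpha float, or
    ``None`` for independent genes); DE sets, selected at random according
    to ``de_spec``, receive only weak correlation and group-specific fold
    changes on their DE genes.  Genes outside any set are independent.

    Returns a :class:`SimulatedStudy` whose ``counts`` is a genes x samples
    DataFrame with sample names ``cond1_1..cond1_n1, cond2_1..cond2_n2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two replicates per group")
    if de_spec is None:
        de_spec = DEInjectionSpec(frac_de_sets=0.0)
    if isinstance(correlation, (int, float)):
        correlation = CorrelationSpec(alpha=float(correlation))
    rng = np.random.default_rng(seed)

    if nb_params is None:
        nb_params = default_nb_params(n_genes, seed=rng.integers(2**31))
    elif len(nb_params) != n_genes:
        raise ValueError("nb_params length must equal n_genes")

    if set_layout is None:
        set_layout = _partition_sets(n_genes, n_sets, set_size, rng)
    else:
        pooled = np.concatenate([np.asarray(v) for v in set_layout.values()])
        if pooled.size != np.unique(pooled).size:
            raise ValueError("gene-sets must be non-overlapping")
        if pooled.size and (pooled.min() < 0 or pooled.max() >= n_genes):
            raise ValueError("set_layout indices out of range")
    set_names = list(set_layout)

    # resolve the non-DE correlation level to a mixing coefficient
    if correlation is None:
        alpha_null = 0.0
    elif correlation.alpha is not None:
        alpha_null = correlation.alpha
    else:
        probe = nb_params.subset(rng.choice(n_genes, size=min(set_size, n_genes), replace=False))
        alpha_null = calibrate_alpha(
            probe, correlation.target_rho, seed=rng.integers(2**31)
        )

    # DE-set correlation range in alpha units
    n_de = int(round(de_spec.frac_de_sets * len(set_names)))
    de_sets = set(rng.choice(set_names, size=n_de, replace=False)) if n_de else set()
    if n_de and de_spec.de_set_rho_range[1] > 0:
        probe = nb_params.subset(rng.choice(n_genes, size=min(set_size, n_genes), replace=False))
        alpha_de_hi = calibrate_alpha(
            probe, de_spec.de_set_rho_range[1], seed=rng.integers(2**31)
        )
        probe_lo = de_spec.de_set_rho_range[0]
        alpha_de_lo = 0.0 if probe_lo == 0 else calibrate_alpha(
            probe, probe_lo, seed=rng.integers(2**31)
        )
    else:
        alpha_de_lo = alpha_de_hi = 0.0

    n_samples = n1 + n2
    group1 = np.arange(n1)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    in_set = np.zeros(n_genes, dtype=bool)

    set_rows, gene_rows = [], []
    gene_ids = np.array([f"gene_{i + 1:05d}" for i in range(n_genes)])

    for name in set_names:
        idx = np.asarray(set_layout[name])
        in_set[idx] = True
        sub = nb_params.subset(idx)
        is_de = name in de_sets
        alpha = (
            float(rng.uniform(alpha_de_lo, alpha_de_hi)) if is_de else alpha_null
        )
        mu_override = None
        de_flag = np.zeros(idx.size, dtype=bool)
        fold = np.full(idx.size, np.nan)
        fold_group = np.zeros(idx.size, dtype=int)
        if is_de:
            frac = rng.uniform(*de_spec.frac_de_genes_range)
            n_de_genes = int(round(frac * idx.size))
            which = rng.choice(idx.size, size=n_de_genes, replace=False)
            de_flag[which] = True
            fold[which] = rng.uniform(*de_spec.fold_range, size=n_de_genes)
            # the group receiving the fold is drawn once per set: a DE
            # set's genes move concordantly, which is what gives the
            # ordinary signed test its full power on true positives
            fold_group[which] = rng.integers(1, 3)
            mu_override = np.broadcast_to(sub.mu[:, None], (idx.size, n_samples)).copy()
            g1 = de_flag & (fold_group == 1)
            g2 = de_flag & (fold_group == 2)
            mu_override[np.ix_(g1, group1)] *= fold[g1][:, None]
            mu_override[np.ix_(g2, np.arange(n1, n_samples))] *= fold[g2][:, None]
        counts[idx] = simulate_correlated_set(
            sub, n_samples, alpha, seed=rng.integers(2**31), mu_override=mu_override
        )
        set_rows.append({"set": name, "is_de": is_de, "alpha": alpha})
        for j in range(idx.size):
            gene_rows.append(
                {
                    "gene": gene_ids[idx[j]],
                    "set": name,
                    "is_de": bool(de_flag[j]),
                    "fold": fold[j],
                    "fold_group": int(fold_group[j]) if de_flag[j] else 0,
                }
            )

    loose = ~in_set
    if loose.any():
        counts[loose] = simulate_independent_counts(
            nb_params.subset(loose), n_samples, seed=rng.integers(2**31)
        )

    samples = [f"cond1_{j + 1}" for j in range(n1)] + [f"cond2_{j + 1}" for j in range(n2)]
    groups = ["cond1"] * n1 + ["cond2"] * n2
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    gene_sets = {name: list(gene_ids[np.asarray(set_layout[name])]) for name in set_names}
    truth = SimTruth(
        set_table=pd.DataFrame(set_rows),
        gene_table=pd.DataFrame(
            gene_rows, columns=["gene", "set", "is_de", "fold", "fold_group"]
        ),
    )
    return SimulatedStudy(counts_df, groups, gene_sets, truth)
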