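# Methods

## The problem

Gene-set enrichment analysis (GSEA) ranks all genes of a two-group
expression study by a differential statistic and asks whether a set's
members concentrate at the extremes of the ranking, via a weighted
Kolmogorov–Smirnov (K-S) running sum.  When replicates are few (2–5 per
group, the norm in bulk RNA-seq), the sample-permuting null is unusable and
the **gene-permuting** (preranked) null is used instead.  Gene permutation,
however, assumes genes are exchangeable.  Genes inside a functional set are
correlated; the variance of any competitive set statistic over a size-K set
with mean pairwise correlation ρ̄ is inflated by

    VIF = 1 + (K − 1) ρ̄,

so at K = 100 and ρ̄ = 0.1 the set statistic is ~11× more variable than the
gene-permutation null believes, and the ordinary test calls a large
fraction of null sets significant.

`absgsea` implements the remedy studied here: score the ranked list of
**absolute** gene statistics with a **one-tailed** (right-tail only) K-S
statistic, and declare a set significant only if it passes an FDR cutoff in
*both* the ordinary signed analysis and the absolute one-tailed analysis.
The absolute one-tailed run has a much better-behaved gene-permutation
null — every permuted set contributes its positive deviation to the null
(none are discarded for having a larger negative excursion), and no set can
be reported "down-regulated" in an analysis where sign has no meaning.  The
intersection keeps the directional interpretation of the ordinary run while
inheriting the false-positive control of the absolute run.

## Enrichment score and null

Genes are ranked by decreasing score r (ties broken by gene identifier —
deterministic; in data and simulations identifiers carry no information
about set membership).  Walking down the list, a member gene advances the
running statistic by |r|^q / N_R (N_R = total member weight, q = 1 by
default; q = 0 gives the classical unweighted K-S statistic) and a
non-member retreats it by 1/(N − N_H).  The standard ES is the deviation of
larger magnitude (positive or negative); the one-tailed absolute ES is the
positive maximum only.  Because the running sum ends at zero, the one-tailed
ES is always ≥ 0.

The gene-permutation null scores random same-size subsets of the same
ranked list — distributionally identical to permuting gene labels — and one
ensemble is shared by all sets of equal size (a large speed-up with no
approximation).  When C(N, K) ≤ 10,000 the null is enumerated exhaustively
instead of sampled.  NES divides each ES by the mean same-sign null ES of
its set size; nominal p-values use add-one smoothing; the FDR q of a set at
NES\* is the pooled-null tail fraction beyond NES\* divided by the observed
tail fraction, clipped to [0, 1] and made monotone non-increasing in |NES|
within each sign (running minimum from the weak end, so q = 0 remains
attainable when an observed ES exceeds every pooled null).

## Gene statistics

All four statistics are computed on median-of-ratios–normalized counts
(raw scale, not log), signed as group 1 minus group 2:

- **mod_t** — moderated t. Per-gene pooled variances are shrunk toward a
  prior by empirical Bayes: the prior degrees of freedom d0 and prior
  variance s0² are obtained by moment-matching the mean and variance of
  log s² across genes (digamma/trigamma inversion; the trigamma inverse is
  found by bracketed root-finding, tolerance 1e-8).  Genes with zero sample
  variance are excluded from the moment fit but still scored with the
  squeezed variance.  d0 = 0 recovers the textbook pooled two-sample t
  (tested to 1e-10); the fit matches `limma::squeezeVar` to ~1e-6 relative.
- **snr** — (μ1 − μ2)/(σ1 + σ2) with each group σ floored at
  max(0.2·|μ_group|, 1e-8), the long-standing convention of GSEA
  implementations; the floor makes near-constant genes finite rather than
  dominant.
- **ranksum** — zero-centered Wilcoxon rank sum Σ_{j∈C1} R_ij − n1(n+1)/2
  with midranks for ties, so its null expectation is exactly 0.
- **logfc** — log2((μ1 + δ)/(μ2 + δ)) where δ is the 5th percentile
  (linear-interpolation quantile) of the pooled non-zero normalized counts;
  the offset only affects logfc.

Gene-sets are intersected with the data's genes and kept when the effective
size lies in [10, 300] (inclusive, configurable).

## The correlated count simulator

Counts are negative binomial with per-gene mean μ and dispersion φ
(variance μ + φμ²; φ = 0 is handled as exact Poisson; sampler size = 1/φ).
Within a set, correlation is induced by one shared uniform per sample:
pushed through each gene's NB quantile function (smallest integer c with
CDF(c) ≥ p) it yields a comonotone count C\*, mixed with the independent
count C as

    M = round((1 − α) C + α C*),      α ∈ [0, 1].

Mixing shrinks the marginal variance by 2α² − 2α + 1, so both C and C\* are
drawn with the inflated dispersion

    φ' = (1 + φμ) / (μ (2α² − 2α + 1)) − 1/μ,

which restores Var(M) = μ + φμ² for every α (φ' = φ at α ∈ {0, 1}).  The
rounding is half-to-even: the mixture lives on a coarse lattice (multiples
of gcd(α, 1−α)), and always rounding .5 ties away from zero would bias the
marginal mean upward by as much as 1.3% (measured at α = 0.25, μ = 10) and
break the conservation the inflated dispersion exists to guarantee.

α maps to a mean pairwise Pearson correlation ρ̄ monotonically but
data-dependently, so requested correlation levels are **calibrated**:
bisection on the empirical α→ρ̄ curve, each probe averaging three simulated
matrices (damping the noise of any single shared-uniform draw), with common
random numbers across probes to keep the empirical curve monotone.
Calibration succeeds when the measurement lands within ±0.02 of the target
and fails explicitly when the target exceeds the correlation achievable at
α = 1 (comonotone counts of unequal genes correlate below 1).

### Benchmark study design

`simulate_study` builds the full benchmark: 10,000 genes, 100
non-overlapping sets of 100 genes (assigned to a *random* subset of gene
identifiers — real identifiers carry no set information, and with heavily
tied discrete scores a contiguous layout would interact with the
deterministic tie-break), two groups with n1/n2 replicates (all size
factors 1).  Optionally 20% of sets are made differentially expressed: a
uniform 20–80% of the set's genes get their group mean multiplied by a
fold drawn uniformly from 1.5–2.0, the receiving group (test or control)
drawn once per set — concordant within-set direction is what gives the
ordinary signed test its full power on true positives, matching the
benchmark's reported power ordering; an anti-conservative per-gene random
direction would instead split a DE set's genes across both ends of the
signed ranking.  DE sets receive only weak correlation (ρ̄ calibrated into
[0, 0.05]); non-DE sets the requested level.  Truth labels (per-set DE
flag, per-gene flags, folds, α used) are returned alongside.

### Default NB parameters

The paper-style estimation of (μ, φ) from a reference cohort is out of
scope; the generator ships a synthetic parameter source:
μ ~ LogNormal(log-mean 5, log-sd 1) truncated below at 10 counts (the usual
low-count filter; median ≈ 150) and φ ~ Gamma(shape 2, scale 0.15)
(mean 0.3, spanning ~0.02–1, the tag-wise range typical of heterogeneous
tumour cohorts).  Any user-supplied (μ, φ) table is accepted.  **Absolute
FPR/power/AUC numbers are parameter-dependent**: with these defaults the
ordinary test's null FPR at ρ̄ = 0.1 (FDR < 0.1, 3 + 3 replicates) averages
≈ 48–51% and its AUC at ρ̄ = 0.6 ≈ 0.50–0.60 across seeds; a parameter
source with a different mean–dispersion profile shifts these by a few
points, while the qualitative contrast with the absolute test (FPR ≈ 1–3%,
AUC ≈ 0.85) is stable.

## Benchmark harness

FPR = fraction of truth-negative sets at q < 0.1, TPR = fraction of
truth-positive sets, AUC via the Mann–Whitney identity on sets ranked by
ascending q with ties broken by descending |NES| (remaining exact ties
score ½ — sets the method cannot distinguish are treated as
indistinguishable).  Metrics are averaged over repetitions; a method
failing on a repetition is warned about and recorded as NaN, not
propagated.  The VIF diagnostic is 1 + (K − 1)ρ̄ with ρ̄ the mean of the
K(K−1)/2 pairwise Pearson correlations of member rows (constant rows
excluded with a warning).  The literature-relevance score of a set is the
mean natural log of per-gene abstract counts, supplied as a table (no
retrieval is performed); zero counts contribute log(0+1) = 0.

## What the simulations do and do not show

The generator reproduces the features that drive the phenomenon under
study — NB marginals with realistic dispersion, controllable exchangeable
within-set correlation, weak-signal DE at small replicate numbers — but
not library-size variation (all size factors 1), mean–dispersion trends,
overlapping pathways, non-exchangeable correlation structure (e.g. blocks
or hubs inside a set) or count-level technical artefacts.  Passing tests
therefore demonstrate the statistical mechanism (correlation inflates the
gene-permutation null's false positives; the absolute one-tailed filter
suppresses them at modest power cost), not calibrated error rates for any
particular real dataset.

## Numerical choices and degenerate inputs

- Ranking ties: stable sort by (score descending, gene id ascending).
- Discrete quantile: smallest integer c with CDF(c) ≥ p.
- N_R = 0 (all member scores zero) is an error naming the set; a set
  containing every ranked gene is an error (p_miss undefined).
- A floating-point tie |max deviation| = |min deviation| resolves to the
  positive side.
- Offset quantile convention: linear interpolation between order
  statistics, pooled over the whole matrix (not per sample).
- Median-of-ratios uses only genes with strictly positive counts in all
  samples; no such gene is an error with guidance.
- Seeds: every stochastic routine takes a seed; equal seeds give
  bit-identical output (tested), and fitted runs derive independent child
  streams for the standard and absolute permutation nulls.

## Problem sizes used by the shipped checks

The acceptance test-suite runs the pure-null and DE benchmarks at the full
design scale (10,000 genes, 100 sets, 1000 permutations) over 20
repetitions — the benchmark's own repetition count — taking ≈ 3 minutes;
`scripts/acceptance.py` reports the same quantities over 5 repetitions
(≈ 1 minute), a scale at which the means are stable to ~1–3 percentage
points.
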