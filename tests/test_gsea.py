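"""Tests of the enrichment engine: ES, permutation null, NES/FDR and the
absolute filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import absgsea as a
from absgsea.gsea import _es_batch


def brute_force_es(scores, members, q=1.0, one_tailed=False):
    """Straightforward reference ES: sort, walk the list, track the
    running p_hit - p_miss.  Independent of the package implementation."""
    order = sorted(scores.keys(), key=lambda g: (-scores[g], g))
    member = set(members)
    nr = sum(abs(scores[g]) ** q for g in member)
    n, nh = len(order), len(member)
    p_hit = p_miss = 0.0
    profile = []
    for g in order:
        if g in member:
            p_hit += abs(scores[g]) ** q / nr
        else:
            p_miss += 1.0 / (n - nh)
        profile.append(p_hit - p_miss)
    mx, mn = max(profile), min(profile)
    if one_tailed:
        return (mx,)
    if abs(abs(mx) - abs(mn)) < 1e-9:
        return (mx, mn)  # floating-point tie: either extremum is valid
    return (mx,) if abs(mx) > abs(mn) else (mn,)


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestEnrichmentScore:
    def test_sole_top_member(self):
        rl = a.rank_genes(_series([3, 2, 1]))
        es, _, lead = a.enrichment_score(rl, ["g0"])
        assert es == pytest.approx(1.0)
        assert lead == ["g0"]

    def test_sole_bottom_member(self):
        rl = a.rank_genes(_series([3, 2, 1]))
        es, _, _ = a.enrichment_score(rl, ["g2"])
        assert es == pytest.approx(-1.0)

    def test_hand_worked_weighted_case(self):
        # scores 3, 1, -2; members {g0, g2}; N_R = 5;
        # running deviations 0.6, -0.4, 0 -> ES = 0.6
        rl = a.rank_genes(_series([3, 1, -2]))
        es, running, _ = a.enrichment_score(rl, ["g0", "g2"])
        assert es == pytest.approx(0.6)
        np.testing.assert_allclose(running, [0.6, -0.4, 0.0])

    def test_one_tailed_truncates_negative_deviation(self):
        # absolute scores of [3, 1, -2] rank genes g0(3), g2(2), g1(1);
        # member {g1} never produces a positive deviation -> ES = 0
        rl = a.rank_genes(_series([3, 1, -2]).abs())
        es, _, _ = a.enrichment_score(rl, ["g1"], one_tailed=True)
        assert es == pytest.approx(0.0)

    def test_one_tailed_equals_two_tailed_when_positive(self):
        rng = np.random.default_rng(0)
        scores = _series(rng.exponential(1.0, 40))
        rl = a.rank_genes(scores)
        for trial in range(10):
            members = list(scores.sample(6, random_state=trial).index)
            two, _, _ = a.enrichment_score(rl, members)
            one, _, _ = a.enrichment_score(rl, members, one_tailed=True)
            assert one >= two - 1e-12
            if two > 0:
                assert one == pytest.approx(two)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(5, 40))
            scores = {f"g{i}": float(rng.standard_normal()) for i in range(n)}
            k = int(rng.integers(1, n))
            members = list(rng.choice(sorted(scores), size=k, replace=False))
            for q in (0.0, 1.0):
                for one_tailed in (False, True):
                    series = pd.Series(scores)
                    rl = a.rank_genes(series.abs() if one_tailed else series, q=q)
                    use = {g: abs(s) for g, s in scores.items()} if one_tailed else scores
                    es, _, _ = a.enrichment_score(rl, members, one_tailed=one_tailed)
                    refs = brute_force_es(use, members, q=q, one_tailed=one_tailed)
                    assert any(es == pytest.approx(r, abs=1e-12) for r in refs)

    def test_batch_path_agrees_with_profile_path(self):
        rng = np.random.default_rng(8)
        scores = _series(rng.standard_normal(60))
        rl = a.rank_genes(scores)
        pos = np.sort(
            np.array([rng.choice(60, size=10, replace=False) for _ in range(50)]), axis=1
        )
        for one_tailed in (False, True):
            batch = _es_batch(pos, rl.weights, 60, one_tailed)
            for row, es_b in zip(pos, batch):
                members = [rl.genes[i] for i in row]
                es, _, _ = a.enrichment_score(rl, members, one_tailed=one_tailed)
                assert es_b == pytest.approx(es, abs=1e-12)

    def test_classical_ks_at_q_zero(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(9)
        scores = _series(rng.standard_normal(30))  # distinct values
        rl = a.rank_genes(scores, q=0.0)
        members = list(scores.sample(8, random_state=2).index)
        es, _, _ = a.enrichment_score(rl, members)
        inside = scores[members]
        outside = scores.drop(members)
        assert abs(es) == pytest.approx(ks_2samp(inside, outside).statistic)

    def test_error_paths(self):
        rl = a.rank_genes(_series([1.0, 0.0, 2.0]))
        with pytest.raises(ValueError, match="N_R = 0"):
            a.enrichment_score(rl, ["g1"])
        with pytest.raises(ValueError, match="strictly smaller"):
            a.enrichment_score(rl, ["g0", "g1", "g2"])
        with pytest.raises(KeyError):
            a.enrichment_score(rl, ["nope"])

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_es_bounds(self, seed):
        """Standard ES lies in [-1, 1]; one-tailed in [0, 1]; the extremes
        are attained exactly when members fill one end of the ranking."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = _series(np.round(rng.standard_normal(n), 3))
        rl = a.rank_genes(scores)
        k = int(rng.integers(1, n))
        members = list(rng.choice(scores.index, size=k, replace=False))
        if sum(abs(scores[m]) for m in members) == 0:
            return
        es, _, _ = a.enrichment_score(rl, members)
        es1, _, _ = a.enrichment_score(rl, members, one_tailed=True)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert -1e-12 <= es1 <= 1.0 + 1e-12
        top = set(rl.genes[:k])
        if set(members) == top and (rl.weights[:k] > 0).all():
            assert es == pytest.approx(1.0)


class TestPermutationNull:
    def test_exhaustive_enumeration(self):
        rl = a.rank_genes(_series([5.0, 4.0, 3.0, 2.0, 1.0, 0.5]))
        nulls = a.gene_permutation_null(rl, [2], n_perm=100, seed=1)
        assert nulls[2].size == math.comb(6, 2)

    def test_monte_carlo_matches_exhaustive_p(self):
        rng = np.random.default_rng(1)
        scores = _series(rng.exponential(1.0, 7))
        rl = a.rank_genes(scores)
        members = list(scores.index[:2])
        es, _, _ = a.enrichment_score(rl, members)
        exact = a.gene_permutation_null(rl, [2], n_perm=100, seed=0)[2]
        p_exact = (np.abs(exact[np.sign(exact) == np.sign(es)]) >= abs(es)).mean()
        mc = a.gene_permutation_null(rl, [2], n_perm=10_000, seed=2, exhaustive_limit=1)[2]
        same = mc[np.sign(mc) == np.sign(es)]
        p_mc = (np.abs(same) >= abs(es)).mean()
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert p_mc == pytest.approx(p_exact, abs=max(2 * se, 1e-3))

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        rl = a.rank_genes(_series(rng.standard_normal(200)))
        n1 = a.gene_permutation_null(rl, [20], n_perm=300, seed=5, exhaustive_limit=1)
        n2 = a.gene_permutation_null(rl, [20], n_perm=300, seed=5, exhaustive_limit=1)
        np.testing.assert_array_equal(n1[20], n2[20])

    def test_minimum_permutations_enforced(self):
        rl = a.rank_genes(_series([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            a.gene_permutation_null(rl, [1], n_perm=10)


class TestNormalizeAndFdr:
    def _observed(self, rl, sets):
        rows = []
        for name, members in sets.items():
            es, _, _ = a.enrichment_score(rl, members)
            rows.append({"set": name, "size": len(members), "es": es})
        return pd.DataFrame(rows)

    def test_identical_sets_get_identical_stats(self):
        rng = np.random.default_rng(3)
        scores = _series(rng.standard_normal(100))
        rl = a.rank_genes(scores)
        members = list(scores.index[::7][:10])
        obs = self._observed(rl, {"s1": members, "s2": members})
        nulls = a.gene_permutation_null(rl, [10], n_perm=200, seed=1, exhaustive_limit=1)
        out = a.normalize_and_fdr(obs, nulls, "standard")
        assert out.loc[0, "nes"] == out.loc[1, "nes"]
        assert out.loc[0, "pval"] == out.loc[1, "pval"]
        assert out.loc[0, "fdr_q"] == out.loc[1, "fdr_q"]

    def test_top_set_beyond_all_nulls_has_zero_fdr(self):
        scores = _series(np.linspace(5, 0.1, 50))
        rl = a.rank_genes(scores)
        # the 5 top-ranked genes: ES near 1, beyond any random null
        obs = self._observed(rl, {"hot": list(scores.index[:5]), "cold": list(scores.index[20:25])})
        nulls = a.gene_permutation_null(rl, [5], n_perm=200, seed=4, exhaustive_limit=1)
        out = a.normalize_and_fdr(obs, nulls, "standard").set_index("set")
        assert out.loc["hot", "fdr_q"] == 0.0

    def test_monotone_q_within_sign(self):
        rng = np.random.default_rng(6)
        scores = _series(rng.standard_normal(300))
        rl = a.rank_genes(scores)
        sets = {
            f"s{i}": list(rng.choice(scores.index, size=15, replace=False))
            for i in range(12)
        }
        obs = self._observed(rl, sets)
        nulls = a.gene_permutation_null(rl, [15], n_perm=200, seed=7, exhaustive_limit=1)
        out = a.normalize_and_fdr(obs, nulls, "standard")
        for sign in (1, -1):
            sub = out[np.sign(out["nes"]) == sign].sort_values(
                "nes", key=lambda s: -s.abs()
            )
            assert (np.diff(sub["fdr_q"]) >= -1e-12).all()


class TestAbsoluteFilter:
    def _two_results(self, seed=0):
        study = a.simulate_study(
            n_genes=500, n_sets=5, set_size=50, correlation=0.4, seed=seed
        )
        std = a.run_gsea(
            study.counts, study.groups, study.gene_sets,
            mode="standard", n_perm=200, seed=1,
        )
        ab = a.run_gsea(
            study.counts, study.groups, study.gene_sets,
            mode="absolute", n_perm=200, seed=1,
        )
        return std, ab

    def test_intersection_semantics(self):
        std, ab = self._two_results()
        merged = a.absolute_filter(std.results, ab.results, 0.25, 0.25)
        sig = set(merged.loc[merged["significant"], "set"])
        s_std = set(std.significant(0.25)["set"])
        s_ab = set(ab.significant(0.25)["set"])
        assert sig == s_std & s_ab

    def test_degenerate_absolute_cutoff_is_identity(self):
        std, ab = self._two_results(seed=1)
        merged = a.absolute_filter(std.results, ab.results, 0.25, 1.1)
        sig = set(merged.loc[merged["significant"], "set"])
        assert sig == set(std.significant(0.25)["set"])

    def test_mismatched_collections_rejected(self):
        std, ab = self._two_results(seed=2)
        with pytest.raises(ValueError, match="different gene-sets"):
            a.absolute_filter(std.results, ab.results.iloc[:-1], 0.1, 0.1)


class TestModelEndToEnd:
    def test_filtered_mode_containment(self, small_study):
        counts, groups, sets, _ = small_study
        model = a.GseaGenePermutation(counts, groups, sets, mode="filtered")
        res = model.fit(n_perm=200, seed=3, fdr=0.25)
        sig = set(res.significant()["set"])
        tab = res.results
        assert sig <= set(tab.loc[tab["q_standard"] < 0.25, "set"])
        assert sig <= set(tab.loc[tab["q_absolute"] < 0.25, "set"])

    def test_absolute_mode_reports_no_downregulated_sets(self, small_study):
        counts, groups, sets, _ = small_study
        res = a.run_gsea(counts, groups, sets, mode="absolute", n_perm=200, seed=4)
        assert (res.results["direction"] != "down").all()
        assert (res.results["es"] >= 0).all()

    def test_two_replicates_per_group_accepted(self):
        study = a.simulate_study(
            n_genes=300, n_sets=3, set_size=40, n1=2, n2=2, correlation=0.2, seed=21
        )
        res = a.run_gsea(
            study.counts, study.groups, study.gene_sets, n_perm=200, seed=5
        )
        assert len(res.results) == 3

    def test_seed_reproducibility(self, small_study):
        counts, groups, sets, _ = small_study
        r1 = a.run_gsea(counts, groups, sets, n_perm=200, seed=9)
        r2 = a.run_gsea(counts, groups, sets, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(r1.results, r2.results)

    def test_summary_mentions_key_facts(self, small_study):
        counts, groups, sets, _ = small_study
        res = a.run_gsea(counts, groups, sets, n_perm=200, seed=10)
        text = res.summary()
        assert "filtered" in text and "mod_t" in text and "200" in text
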