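import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methnome as mn
from methnome import _hmm
from methnome.ndr import (
    BinomialHmm,
    NdrCaller,
    call_ndrs,
    compute_efdr,
    fisher_flank_test,
    fisher_greater_pvalues,
    segment,
    shuffle_gch,
    summarize_peaks,
)
from methnome.regions import GenomicRegion, RegionSet, reciprocal_overlap_recovery


def _gch_table(pos, meth, total, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "context": "GCH", "meth": meth, "total": total}
    )


def _sample_hmm(rng, n, p_open=0.5, p_closed=0.05, stay=0.98, coverage=15):
    states = np.empty(n, dtype=int)
    states[0] = 1
    for i in range(1, n):
        states[i] = states[i - 1] if rng.random() < stay else 1 - states[i - 1]
    total = rng.poisson(coverage, n)
    p = np.where(states == 0, p_open, p_closed)
    meth = rng.binomial(total, p)
    return states, meth.astype(float), total.astype(float)


class TestBinomialHmm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(61)
        _, meth, total = _sample_hmm(rng, 10_000)
        hmm = BinomialHmm().fit(_gch_table(np.arange(10_000) * 10, meth, total))
        assert hmm.p_open_ == pytest.approx(0.5, abs=0.03)
        assert hmm.p_closed_ == pytest.approx(0.05, abs=0.03)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(62)
        _, meth, total = _sample_hmm(rng, 3000)
        hmm = BinomialHmm().fit(_gch_table(np.arange(3000) * 10, meth, total))
        assert (np.diff(hmm.loglik_history_) >= -1e-6).all()

    def test_homogeneous_data_collapses_states(self):
        rng = np.random.default_rng(63)
        total = rng.poisson(20, 5000)
        meth = rng.binomial(total, 0.1)
        hmm = BinomialHmm().fit(_gch_table(np.arange(5000) * 10, meth, total))
        assert abs(hmm.p_open_ - hmm.p_closed_) < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 10"):
            BinomialHmm().fit(_gch_table([1, 2], [0, 1], [1, 1]))
        with pytest.raises(ValueError, match="zero coverage"):
            BinomialHmm().fit(_gch_table(np.arange(20), [0] * 20, [0] * 20))

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(64)
        _, meth, total = _sample_hmm(rng, 2000)
        hmm = BinomialHmm().fit(_gch_table(np.arange(2000) * 10, meth, total))
        gamma = hmm.predict_proba(_gch_table(np.arange(2000) * 10, meth, total))
        assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-9


def _enumerate_paths(meth, total, p, A, pi):
    """Brute-force total likelihood and best path over all 2^n paths."""
    best_lp, best_path, tot = -np.inf, None, 0.0
    n = len(meth)
    for path in itertools.product([0, 1], repeat=n):
        lp = math.log(pi[path[0]])
        for i in range(1, n):
            lp += math.log(A[path[i - 1], path[i]])
        for i, s in enumerate(path):
            m, t = meth[i], total[i]
            lp += (
                math.lgamma(t + 1) - math.lgamma(m + 1) - math.lgamma(t - m + 1)
                + m * math.log(p[s]) + (t - m) * math.log(1 - p[s])
            )
        tot += math.exp(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return math.log(tot), np.array(best_path)


class TestAgainstPathEnumeration:
    def test_forward_equals_sum_over_paths_on_toy(self):
        meth = np.array([3.0, 0.0, 1.0, 5.0])
        total = np.array([6.0, 8.0, 7.0, 6.0])
        p = np.array([0.5, 0.05])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([0.4, 0.6])
        ll = _hmm.forward_loglik(meth, total, p[0], p[1], A, pi)
        expected, _ = _enumerate_paths(meth, total, p, A, pi)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_viterbi_equals_argmax_over_paths(self):
        rng = np.random.default_rng(65)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            total = rng.poisson(12, n).astype(float)
            meth = rng.binomial(total.astype(int), rng.uniform(0.05, 0.5, n)).astype(float)
            p = np.sort(rng.uniform(0.02, 0.6, 2))[::-1]
            A = np.array([[0.9, 0.1], [0.2, 0.8]])
            pi = np.array([0.3, 0.7])
            _, best = _enumerate_paths(meth, total, p, A, pi)
            assert np.array_equal(_hmm.viterbi(meth, total, p[0], p[1], A, pi), best)


class TestSegmentation:
    def test_all_background_decode(self):
        rng = np.random.default_rng(66)
        total = rng.poisson(20, 500)
        meth = rng.binomial(total, 0.05)
        tab = _gch_table(np.arange(500) * 10, meth, total)
        hmm = BinomialHmm(p_open_init=0.5, p_closed_init=0.05, max_iter=0)
        hmm.p_open_, hmm.p_closed_ = 0.5, 0.05
        hmm.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
        hmm.startprob_ = np.array([0.5, 0.5])
        ndrs, background = segment(tab, hmm)
        assert len(ndrs) == 0
        assert len(background) == 1
        assert (background[0].start, background[0].end) == (0, 4991)

    def test_planted_block_recovered(self, small_genome):
        genome, catalog = small_genome
        params = mn.SimulationParams(genome_length=50_000, n_ndrs=(2, 2), rng_seed=67)
        table, truth = mn.simulate_nome(genome, catalog, params)
        sub = table[(table["sample_id"] == "monocyte") & (table["context"] == "GCH")]
        hmm = BinomialHmm().fit(sub)
        ndrs, _ = segment(sub, hmm)
        for r in truth.planted_ndrs["monocyte"]:
            assert any(r.reciprocal_overlap(c) >= 0.5 for c in ndrs)


class TestFisherFlank:
    def test_matches_hypergeometric_tail_and_is_small(self):
        p = float(fisher_greater_pvalues(30, 10, 10, 70))

        def brute(a, b, c, d):
            M, K, n = a + b + c + d, a + c, a + b
            return sum(
                math.comb(K, k) * math.comb(M - K, n - k)
                for k in range(a, min(K, n) + 1)
            ) / math.comb(M, n)

        assert p == pytest.approx(brute(30, 10, 10, 70), abs=1e-12)
        assert p < 1e-6

    def test_equal_rates_give_large_p(self):
        assert float(fisher_greater_pvalues(20, 20, 20, 20)) >= 0.5

    def test_zero_inside_total_is_dropped(self):
        tab = _gch_table([10, 20, 100, 110], [1, 1, 1, 1], [0, 0, 5, 5])
        ndr = GenomicRegion("chr1", 5, 25)
        assert fisher_flank_test(ndr, tab, flank_bp=100) is None

    def test_flanks_clip_at_neighbours(self):
        pos = np.arange(0, 300, 10)
        tab = _gch_table(pos, [2] * 30, [10] * 30)
        ndr = GenomicRegion("chr1", 100, 150)
        p, (im, it, fm, ft) = fisher_flank_test(
            ndr, tab, flank_bp=1000, left_bound=80, right_bound=180
        )
        # flank width min(len, 1000) = 50 but clipped to [80,100) and [150,180)
        assert it == sum(10 for x in pos if 100 <= x < 150)
        assert ft == sum(10 for x in pos if 80 <= x < 100 or 150 <= x < 180)


class TestShuffle:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_preserves_value_multiset(self, seed):
        rng = np.random.default_rng(68)
        total = rng.integers(0, 30, 200)
        tab = _gch_table(np.arange(200) * 10, rng.binomial(total, 0.2), total)
        shuf = shuffle_gch(tab, seed)
        assert sorted(map(tuple, shuf[["meth", "total"]].to_numpy())) == sorted(
            map(tuple, tab[["meth", "total"]].to_numpy())
        )
        assert (shuf["pos"].to_numpy() == tab["pos"].to_numpy()).all()

    def test_two_seeds_differ(self):
        rng = np.random.default_rng(69)
        total = rng.integers(1, 30, 500)
        tab = _gch_table(np.arange(500) * 10, rng.binomial(total, 0.3), total)
        s1 = shuffle_gch(tab, 1)
        s2 = shuffle_gch(tab, 2)
        assert not (s1["meth"].to_numpy() == s2["meth"].to_numpy()).all()
        assert s1["meth"].sum() == s2["meth"].sum() == tab["meth"].sum()


class TestEfdr:
    def test_no_null_below_observed_gives_zero(self):
        efdr = compute_efdr([1e-10, 1e-8], [0.5, 0.6, 0.7], n_shuffles=1)
        assert (efdr == 0).all()

    def test_self_null_gives_efdr_near_one(self):
        rng = np.random.default_rng(70)
        obs = rng.uniform(size=200)
        efdr = compute_efdr(obs, obs, n_shuffles=1)
        assert np.median(efdr) > 0.9

    def test_monotone_in_p(self):
        rng = np.random.default_rng(71)
        obs = rng.uniform(size=100)
        null = rng.uniform(size=300)
        efdr = compute_efdr(obs, null, n_shuffles=3)
        order = np.argsort(obs)
        assert (np.diff(efdr[order]) >= 0).all()

    def test_invariant_under_duplicating_shuffles(self):
        rng = np.random.default_rng(72)
        obs = rng.uniform(size=50)
        null = rng.uniform(size=100)
        e1 = compute_efdr(obs, null, n_shuffles=2)
        e2 = compute_efdr(obs, np.concatenate([null, null]), n_shuffles=4)
        assert np.allclose(e1, e2)

    def test_requires_shuffles(self):
        with pytest.raises(ValueError):
            compute_efdr([0.5], [0.1], n_shuffles=0)


class TestCallNdrs:
    def test_deterministic_under_seed(self, small_genome):
        genome, catalog = small_genome
        params = mn.SimulationParams(genome_length=50_000, n_ndrs=(3, 3), rng_seed=73)
        table, _ = mn.simulate_nome(genome, catalog, params)
        sub = table[table["sample_id"] == "monocyte"]
        k1, c1 = call_ndrs(sub, n_shuffles=3, seed=5)
        k2, c2 = call_ndrs(sub, n_shuffles=3, seed=5)
        assert [(c.start, c.end, c.fisher_p, c.efdr) for c in c1] == [
            (c.start, c.end, c.fisher_p, c.efdr) for c in c2
        ]

    def test_rejects_multisample_table(self, small_genome):
        genome, catalog = small_genome
        params = mn.SimulationParams(genome_length=50_000, n_ndrs=(2, 2), rng_seed=74)
        table, _ = mn.simulate_nome(genome, catalog, params)
        with pytest.raises(ValueError, match="per sample"):
            call_ndrs(table)

    def test_macrophage_has_more_peaks_than_monocyte(self):
        """With more planted NDRs in macrophage, both the called count and
        the covered bp are larger there (direction of the real contrast)."""
        params = mn.SimulationParams(genome_length=150_000, n_ndrs=(3, 6), rng_seed=75)
        genome, catalog = mn.simulate_genome(params)
        table, _ = mn.simulate_nome(genome, catalog, params)
        results = {}
        for ct in ("monocyte", "macrophage"):
            caller = NdrCaller(seed=8).fit(table[table["sample_id"] == ct])
            results[ct] = summarize_peaks(caller.regions_)
        assert results["macrophage"][0] > results["monocyte"][0]
        assert results["macrophage"][1] > results["monocyte"][1]


class TestSummarizePeaks:
    def test_disjoint_and_empty(self):
        rs = RegionSet([GenomicRegion("chr1", 0, 100), GenomicRegion("chr1", 200, 300)])
        assert summarize_peaks(rs) == (2, 200)
        assert summarize_peaks(RegionSet()) == (0, 0)

    def test_matches_bruteforce_merge(self):
        rng = np.random.default_rng(76)
        regions = RegionSet(
            GenomicRegion("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 50_000, 1000), rng.integers(1, 400, 1000))
        )
        count, bp = summarize_peaks(regions)
        covered = np.zeros(60_000, dtype=bool)
        for r in regions:
            covered[r.start : r.end] = True
        assert bp == int(covered.sum())
        # count = number of maximal covered runs
        runs = int(np.sum(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])) == 1))
        assert count == runs
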