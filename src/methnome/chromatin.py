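"""Histone-signature matrices and k-means clustering at regulatory regions.

Regions are represented as binned log2(ChIP/input) profiles over the region
body (rescaled to a fixed 1 kb = 40 x 25 bp bins) plus unscaled 1 kb flanks
on each side, across six histone marks and two cell types. Regions are
clustered by k-means (k = 3 by default) on all bins jointly, and
cluster-by-mark differentiation changes are assessed with paired Student's
t-tests on per-region mean signal (macrophage minus monocyte), Bonferroni
corrected over all (cluster, mark) tests at alpha 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .meth_io import PipelineConfig
from .regions import RegionSet

BODY_BINS = 40
FLANK_BINS = 40


def _binned_track(
    counts: pd.DataFrame, chrom: str, bin_size: int, n_bins_needed: int
) -> np.ndarray:
    """Dense per-bin count vector for one chromosome (missing bins are 0)."""
    sub = counts[counts["chrom"] == chrom]
    out = np.zeros(n_bins_needed)
    idx = (sub["bin_start"] // bin_size).to_numpy()
    ok = (idx >= 0) & (idx < n_bins_needed)
    out[idx[ok]] = sub["count"].to_numpy()[ok]
    return out


def _region_profile(
    track: np.ndarray,
    total: float,
    input_track: np.ndarray,
    input_total: float,
    start: int,
    end: int,
    bin_size: int,
    flank_bp: int,
    pseudocount: float,
) -> np.ndarray:
    """log2 ratio profile: 40 left-flank bins, body rescaled to 40 bins by
    linear interpolation, 40 right-flank bins. Bins outside the contig are
    NaN."""
    n_bins = len(track)

    def log2ratio(bin_lo: int, bin_hi: int) -> np.ndarray:
        vals = np.full(bin_hi - bin_lo, np.nan)
        lo = max(bin_lo, 0)
        hi = min(bin_hi, n_bins)
        if hi > lo:
            chip = track[lo:hi] / total + pseudocount
            inp = input_track[lo:hi] / input_total + pseudocount
            vals[lo - bin_lo: hi - bin_lo] = np.log2(chip / inp)
        return vals

    b0, b1 = start // bin_size, -(-end // bin_size)  # body bin span (ceil end)
    left = log2ratio(b0 - FLANK_BINS, b0)
    right = log2ratio(b1, b1 + FLANK_BINS)
    body_raw = log2ratio(b0, b1)
    if len(body_raw) == BODY_BINS:
        body = body_raw
    else:
        x_old = np.linspace(0.0, 1.0, len(body_raw))
        x_new = np.linspace(0.0, 1.0, BODY_BINS)
        if np.isnan(body_raw).any():
            ok = ~np.isnan(body_raw)
            body = (
                np.interp(x_new, x_old[ok], body_raw[ok])
                if ok.any()
                else np.full(BODY_BINS, np.nan)
            )
        else:
            body = np.interp(x_new, x_old, body_raw)
    return np.concatenate([left, body, right])


def build_signal_matrix(
    regions: RegionSet,
    chip_counts: Mapping[tuple[str, str], tuple[pd.DataFrame, float]],
    input_counts: Mapping[str, tuple[pd.DataFrame, float]],
    config: Optional[PipelineConfig] = None,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Region x (mark, cell type, bin) log2(ChIP/input) matrix.

    ``chip_counts`` maps ``(mark, cell_type)`` to ``(bin table, library
    total)`` where the bin table has columns ``chrom, bin_start, count``;
    ``input_counts`` maps ``cell_type`` to its input track. Counts are
    normalised by the library totals before the ratio, so doubling every
    count and the total together leaves the matrix unchanged. The region
    body is rescaled to 40 bins; 1 kb flanks contribute 40 unscaled bins
    each side (bins beyond a contig end are NaN).
    """
    config = config or PipelineConfig()
    bs = config.bin_size_bp
    chroms = {r.chrom for r in regions}
    max_end = {c: max(r.end for r in regions if r.chrom == c) + config.flank_bp for c in chroms}
    n_bins = {c: -(-max_end[c] // bs) + 1 for c in chroms}

    marks = sorted({m for m, _ in chip_counts})
    cts = sorted({ct for _, ct in chip_counts})
    dense_chip = {
        key: {c: _binned_track(tab, c, bs, n_bins[c]) for c in chroms}
        for key, (tab, _) in chip_counts.items()
    }
    dense_input = {
        ct: {c: _binned_track(tab, c, bs, n_bins[c]) for c in chroms}
        for ct, (tab, _) in input_counts.items()
    }
    cols = pd.MultiIndex.from_product(
        [marks, cts, range(FLANK_BINS + BODY_BINS + FLANK_BINS)],
        names=["mark", "cell_type", "bin"],
    )
    values = np.empty((len(regions), len(cols)))
    width = FLANK_BINS + BODY_BINS + FLANK_BINS
    for i, r in enumerate(regions):
        j = 0
        for mark in marks:
            for ct in cts:
                values[i, j: j + width] = _region_profile(
                    dense_chip[(mark, ct)][r.chrom],
                    chip_counts[(mark, ct)][1],
                    dense_input[ct][r.chrom],
                    input_counts[ct][1],
                    r.start,
                    r.end,
                    bs,
                    config.flank_bp,
                    pseudocount,
                )
                j += width
    return pd.DataFrame(values, columns=cols)


def cluster_regions(
    matrix: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """k-means labels (1..k) over the full bin matrix.

    Missing bins are imputed as row means first. The best of ``n_restarts``
    initialisations (by inertia) is kept, and labels are canonicalised by
    descending cluster size so a fixed seed yields reproducible numbering.
    """
    if k > len(matrix):
        raise ValueError(f"k = {k} exceeds the {len(matrix)} regions")
    X = matrix.to_numpy(dtype=float).copy()
    if np.isnan(X).any():
        row_means = np.nanmean(X, axis=1)
        rows, cols = np.nonzero(np.isnan(X))
        X[rows, cols] = row_means[rows]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="mergesort")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[raw]


def per_region_mark_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean bin value per region for each (mark, cell_type)."""
    return matrix.T.groupby(level=["mark", "cell_type"]).mean().T


@dataclass
class MarkTestResult:
    cluster: int
    mark: str
    mean_change: float
    t_stat: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    n_regions: int
    skipped: bool = False


def cluster_mark_tests(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.001,
    celltype_pair: tuple[str, str] = ("monocyte", "macrophage"),
) -> list[MarkTestResult]:
    """Paired t-tests of per-region mean signal change per (cluster, mark).

    For every cluster and mark, the per-region mean bin values of the second
    cell type are compared to the first with a paired Student's t-test;
    p-values are Bonferroni-corrected over all performed (cluster, mark)
    tests and flagged significant when the adjusted p < ``alpha``. Clusters
    with fewer than two regions are skipped (flagged).
    """
    means = per_region_mark_means(matrix)
    marks = sorted({m for m, _ in means.columns})
    clusters = sorted(np.unique(labels))
    ct1, ct2 = celltype_pair
    results: list[MarkTestResult] = []
    for cl in clusters:
        mask = labels == cl
        for mark in marks:
            if mask.sum() < 2:
                results.append(
                    MarkTestResult(cl, mark, np.nan, np.nan, np.nan, np.nan,
                                   False, int(mask.sum()), skipped=True)
                )
                continue
            a = means.loc[mask, (mark, ct2)].to_numpy()
            b = means.loc[mask, (mark, ct1)].to_numpy()
            delta = a - b
            if np.allclose(delta, delta[0]):
                # zero-variance pairs: p degenerates to 1 (no change) or 0
                if abs(delta[0]) < 1e-12:
                    t, p = 0.0, 1.0
                else:
                    t, p = float(np.sign(delta[0]) * np.inf), 0.0
            else:
                t, p = stats.ttest_rel(a, b)
            results.append(
                MarkTestResult(cl, mark, float(delta.mean()), float(t), float(p),
                               np.nan, False, int(mask.sum()))
            )
    n_tests = sum(1 for r in results if not r.skipped)
    for r in results:
        if not r.skipped:
            r.p_bonferroni = min(1.0, r.p_raw * n_tests)
            r.significant = r.p_bonferroni < alpha
    return results


class ChromatinClusterer(BaseEstimator):
    """k-means signature clustering plus per-cluster mark tests.

    Attributes after ``fit(matrix)``: ``labels_`` (1..k per region) and
    ``mark_tests_`` (list of :class:`MarkTestResult`).
    """

    def __init__(self, k: int = 3, seed: int = 0, n_restarts: int = 10,
                 alpha: float = 0.001) -> None:
        self.k = k
        self.seed = seed
        self.n_restarts = n_restarts
        self.alpha = alpha

    def fit(self, matrix: pd.DataFrame) -> "ChromatinClusterer":
        self.labels_ = cluster_regions(matrix, self.k, self.seed, self.n_restarts)
        cts = sorted({ct for _, ct, _ in matrix.columns})
        pair = ("monocyte", "macrophage") if set(cts) == {"monocyte", "macrophage"} else tuple(cts[:2])
        self.mark_tests_ = cluster_mark_tests(matrix, self.labels_, self.alpha, pair)
        return self

    def fit_predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.fit(matrix).labels_

    def tests_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.mark_tests_])
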