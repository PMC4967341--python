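"""Smoothing-based differential methylation region (DMR) calling.

The procedure follows the BSmooth recipe at count level: per-sample
kernel-smoothed methylation curves, a t-like per-CpG statistic on the
smoothed group difference with a variance floor, Benjamini-Hochberg q-values
against a standard-normal reference, and region formation as maximal runs of
same-sign significant CpGs filtered on size (>= 4 CpGs) and group mean
smoothed difference (>= 0.3 by default).

The smoothing window defaults (2000 bp / 70 CpGs) are appropriate for a
mammalian CpG density; on dense toy genomes the window should be scaled to
the CpG spacing (see the package methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .meth_io import PipelineConfig
from .regions import GenomicRegion, RegionSet


@dataclass
class DmrCall:
    """One called DMR: coordinates, CpG count, group mean smoothed
    difference (group1 - group2) and direction (loss = methylation lower in
    group 2)."""

    region: GenomicRegion
    n_cpgs: int
    mean_diff: float
    direction: str
    mean_stat: float

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def smooth_methylation(
    table: pd.DataFrame,
    window_bp: int = 2000,
    min_sites: int = 70,
    degree: int = 0,
) -> pd.DataFrame:
    """Kernel smoothing of per-sample methylation fractions.

    At each CpG the smoothed value is a tricube-distance, coverage-weighted
    local fit to the raw fractions over a window of at least ``window_bp``
    (total span) containing at least ``min_sites`` CpGs; chromosome
    boundaries are never crossed. Chromosomes with fewer than ``min_sites``
    CpGs are smoothed over all available sites.

    ``degree`` 0 (default) takes the weighted mean; ``degree`` 1 fits a
    weighted local line and evaluates it at the site, which removes the
    attenuation a plain mean suffers at sharp methylation boundaries (the
    local-polynomial boundary correction; it falls back to the mean when the
    window geometry is degenerate).

    Returns a wide DataFrame indexed by (chrom, pos) with one ``raw_<sample>``
    and one ``smooth_<sample>`` column per sample.
    """
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    half = window_bp / 2.0
    pieces = []
    samples = sorted(table["sample_id"].unique())
    for chrom, sub in table.groupby("chrom", sort=True):
        wide_m = sub.pivot_table(index="pos", columns="sample_id", values="meth")
        wide_t = sub.pivot_table(index="pos", columns="sample_id", values="total")
        pos = wide_m.index.to_numpy(dtype=float)
        n = len(pos)
        out = {"chrom": chrom, "pos": wide_m.index.to_numpy()}
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        need = min(min_sites, n)
        for s in samples:
            meth = wide_m[s].to_numpy(dtype=float)
            total = wide_t[s].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
            smooth = np.empty(n)
            for i in range(n):
                a, b = lo[i], hi[i]
                # expand symmetrically (by nearest site) to reach min_sites
                while b - a < need:
                    left_d = pos[i] - pos[a - 1] if a > 0 else np.inf
                    right_d = pos[b] - pos[i] if b < n else np.inf
                    if left_d <= right_d:
                        a -= 1
                    else:
                        b += 1
                dx = pos[a:b] - pos[i]
                d = np.abs(dx)
                dmax = max(d.max(), half)
                w = _tricube(d / (dmax * 1.0001)) * total[a:b]
                f = frac[a:b]
                ok = np.isfinite(f) & (w > 0)
                if not ok.any():
                    smooth[i] = np.nan
                    continue
                wk, fk, xk = w[ok], f[ok], dx[ok]
                if degree == 1:
                    s0 = wk.sum()
                    s1 = (wk * xk).sum()
                    s2 = (wk * xk * xk).sum()
                    det = s0 * s2 - s1 * s1
                    if det > 1e-12 * max(s0 * s2, 1e-300):
                        # intercept of the weighted least-squares line at dx=0
                        smooth[i] = ((s2 - xk * s1) * wk * fk).sum() / det
                        continue
                smooth[i] = np.average(fk, weights=wk)
            out[f"raw_{s}"] = frac
            out[f"smooth_{s}"] = np.clip(smooth, 0.0, 1.0)
        pieces.append(pd.DataFrame(out))
    return pd.concat(pieces, ignore_index=True)


def per_cpg_statistic(
    smoothed: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    sd_floor_quantile: float = 0.75,
    sd_smooth_sites: int = 101,
) -> pd.DataFrame:
    """Signed t-like statistic and BH q-value per CpG.

    The statistic is the group difference of mean smoothed fractions divided
    by a locally pooled standard deviation that is floored at the
    ``sd_floor_quantile`` quantile of all per-site SDs and then smoothed
    with a running mean over ``sd_smooth_sites`` CpGs (few-sample SD
    estimates are chi-noisy in both directions; flooring removes the
    under-estimates, smoothing the over-estimates). Two-sided p-values use a
    standard-normal reference and are BH-adjusted genome-wide. With one
    sample per group the SD degrades to the genome-wide SD of the smoothed
    difference (flagged via the ``pooled_background`` attribute on the
    result).
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups need at least one sample")
    g1 = smoothed[[f"smooth_{s}" for s in group1]].to_numpy()
    g2 = smoothed[[f"smooth_{s}" for s in group2]].to_numpy()
    n1, n2 = g1.shape[1], g2.shape[1]
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    pooled_background = n1 < 2 or n2 < 2
    if pooled_background:
        sd = np.full(diff.shape, max(float(np.nanstd(diff)), 1e-8))
    else:
        v1 = g1.var(axis=1, ddof=1)
        v2 = g2.var(axis=1, ddof=1)
        sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        floor = np.nanquantile(sd, sd_floor_quantile)
        sd = np.maximum(sd, max(floor, 1e-8))
        if sd_smooth_sites > 1:
            sd = (
                pd.Series(sd)
                .groupby(smoothed["chrom"].to_numpy())
                .transform(
                    lambda s: s.rolling(sd_smooth_sites, center=True, min_periods=1).mean()
                )
                .to_numpy()
            )
    stat = diff / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    finite = np.isfinite(pvals)
    qvals = np.full(pvals.shape, np.nan)
    if finite.any():
        qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    out = smoothed[["chrom", "pos"]].copy()
    out["diff"] = diff
    out["stat"] = stat
    out["p"] = pvals
    out["q"] = qvals
    out.attrs["pooled_background"] = pooled_background
    return out


def find_dmrs(
    site_stats: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    max_gap: int = 300,
) -> list[DmrCall]:
    """Form DMRs from per-CpG statistics.

    A candidate is a maximal run of same-sign CpGs with q <= ``dmr_q_cutoff``
    whose consecutive members lie within ``max_gap`` bp of each other
    (intervening non-significant CpGs do not break a run); candidates are
    kept when they contain >= ``dmr_min_cpgs`` significant CpGs and the
    absolute group mean smoothed difference over the run is >=
    ``dmr_min_diff``. The region spans the first to last CpG of the run (end
    exclusive = last + 1). No region-level p-value is attached.
    """
    config = config or PipelineConfig()
    calls: list[DmrCall] = []
    for chrom, sub in site_stats.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        keep = (
            (sub["q"].to_numpy() <= config.dmr_q_cutoff)
            & np.isfinite(sub["stat"].to_numpy())
            & (sub["stat"].to_numpy() != 0)
        )
        sig = sub[keep]
        pos = sig["pos"].to_numpy()
        stat = sig["stat"].to_numpy()
        diff = sig["diff"].to_numpy()
        i = 0
        n = len(pos)
        while i < n:
            j = i + 1
            while (
                j < n
                and np.sign(stat[j]) == np.sign(stat[i])
                and pos[j] - pos[j - 1] <= max_gap
            ):
                j += 1
            run = slice(i, j)
            n_cpgs = j - i
            mean_diff = float(np.mean(diff[run]))
            if n_cpgs >= config.dmr_min_cpgs and abs(mean_diff) >= config.dmr_min_diff:
                region = GenomicRegion(chrom, int(pos[i]), int(pos[j - 1]) + 1)
                calls.append(
                    DmrCall(
                        region=region,
                        n_cpgs=n_cpgs,
                        mean_diff=mean_diff,
                        direction="loss" if mean_diff > 0 else "gain",
                        mean_stat=float(np.mean(stat[run])),
                    )
                )
            i = j
    return calls


def region_mean_methylation(
    table: pd.DataFrame, regions: RegionSet
) -> pd.DataFrame:
    """Coverage-weighted mean methylated fraction per region per sample.

    Sites with total 0 are excluded; a region with no covered CpGs yields a
    missing value (NaN), never zero.
    """
    samples = sorted(table["sample_id"].unique())
    rows = []
    for i, r in enumerate(regions):
        sub = table[
            (table["chrom"] == r.chrom)
            & (table["pos"] >= r.start)
            & (table["pos"] < r.end)
            & (table["total"] > 0)
        ]
        row: dict = {"region": r.attrs.get("name", f"region{i + 1}"),
                     "chrom": r.chrom, "start": r.start, "end": r.end}
        for s in samples:
            ss = sub[sub["sample_id"] == s]
            row[s] = (
                float(ss["meth"].sum() / ss["total"].sum()) if len(ss) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


class DmrCaller(BaseEstimator):
    """Two-group DMR caller (scikit-learn-style estimator).

    Parameters
    ----------
    min_diff : float
        Minimum absolute group mean smoothed difference (default 0.3).
    min_cpgs : int
        Minimum CpGs per DMR (default 4).
    q_cutoff : float
        Per-CpG BH q-value cutoff (default 1e-4).
    max_gap : int
        Maximum gap between consecutive DMR CpGs in bp (default 300).
    window_bp, min_sites :
        Smoothing window (see :func:`smooth_methylation`).

    Attributes
    ----------
    smoothed_ : DataFrame of raw and smoothed fractions.
    site_stats_ : DataFrame of per-CpG statistic, p and q.
    dmrs_ : list of :class:`DmrCall`.
    """

    def __init__(
        self,
        min_diff: float = 0.3,
        min_cpgs: int = 4,
        q_cutoff: float = 1e-4,
        max_gap: int = 300,
        window_bp: int = 2000,
        min_sites: int = 70,
        degree: int = 1,
    ) -> None:
        self.min_diff = min_diff
        self.min_cpgs = min_cpgs
        self.q_cutoff = q_cutoff
        self.max_gap = max_gap
        self.window_bp = window_bp
        self.min_sites = min_sites
        self.degree = degree

    def fit(
        self,
        table: pd.DataFrame,
        group1: Sequence[str],
        group2: Sequence[str],
        exclude_gcg: bool = False,
    ) -> "DmrCaller":
        """Call DMRs between two groups of samples in ``table``.

        ``exclude_gcg`` drops GCG-context CpGs first (required for tables
        derived from NOMe-seq material, where GCG is ambiguous).
        """
        sub = table[table["sample_id"].isin(list(group1) + list(group2))]
        if exclude_gcg:
            sub = sub[sub["context"] != "GCG"]
        self.smoothed_ = smooth_methylation(sub, self.window_bp, self.min_sites, self.degree)
        self.site_stats_ = per_cpg_statistic(self.smoothed_, group1, group2)
        cfg = PipelineConfig(
            dmr_min_diff=self.min_diff,
            dmr_min_cpgs=self.min_cpgs,
            dmr_q_cutoff=self.q_cutoff,
        )
        self.dmrs_ = find_dmrs(self.site_stats_, cfg, self.max_gap)
        return self

    @property
    def regions_(self) -> RegionSet:
        return RegionSet(
            GenomicRegion(
                d.chrom, d.start, d.end,
                {"name": f"DMR{i + 1}", "n_cpgs": d.n_cpgs,
                 "mean_diff": d.mean_diff, "direction": d.direction},
            )
            for i, d in enumerate(self.dmrs_)
        )


def threshold_sweep(
    site_stats: pd.DataFrame,
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    config: Optional[PipelineConfig] = None,
    max_gap: int = 300,
) -> pd.DataFrame:
    """DMR counts across minimum-difference thresholds (the looser the
    threshold the more regions; counts are non-increasing in the cutoff)."""
    config = config or PipelineConfig()
    rows = []
    for t in thresholds:
        cfg = PipelineConfig(
            dmr_min_diff=t,
            dmr_min_cpgs=config.dmr_min_cpgs,
            dmr_q_cutoff=config.dmr_q_cutoff,
        )
        rows.append({"min_diff": t, "n_dmrs": len(find_dmrs(site_stats, cfg, max_gap))})
    return pd.DataFrame(rows)
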