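"""NOMe-seq nucleosome-depleted-region (NDR) calling.

The genome's GCH methylation profile is segmented with a two-state binomial
hidden Markov model (open/accessible vs closed/background) fitted by
Baum-Welch and decoded by Viterbi. Each putative NDR is contrasted against
its flanking background with a one-sided Fisher's exact test (accessibility
means elevated GCH methylation inside), and p-values are converted to
empirical false-discovery rates (eFDR) by re-running segmentation + testing
on tables whose (meth, total) values were shuffled across GCH positions.
Only NDRs with eFDR below the cutoff (default 0.01) are kept.

GCG-context sites (ambiguous between endogenous CpG and enzymatic GpC
methylation) are excluded at module entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import _hmm
from .meth_io import PipelineConfig
from .regions import GenomicRegion, RegionSet

logger = logging.getLogger(__name__)


@dataclass
class NdrCall:
    """A candidate NDR with its Fisher flank contrast and empirical FDR."""

    region: GenomicRegion
    n_gch: int
    inside_meth: int
    inside_total: int
    flank_meth: int
    flank_total: int
    fisher_p: float
    efdr: float = float("nan")

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


class BinomialHmm(BaseEstimator):
    """Two-state binomial-emission HMM (open vs closed chromatin).

    Parameters are Baum-Welch initial values; ``fit`` runs EM on per-site
    (meth, total) pairs until the log-likelihood improves by less than
    ``tol`` or ``max_iter`` is reached. States are canonicalised after
    fitting so that state 0 is the open state (``p_open_ > p_closed_``).

    Attributes
    ----------
    p_open_, p_closed_ : fitted emission success probabilities.
    transmat_ : 2x2 transition matrix (row 0 = open).
    startprob_ : initial state distribution.
    loglik_history_ : per-iteration log-likelihood (non-decreasing).
    """

    def __init__(
        self,
        p_open_init: float = 0.3,
        p_closed_init: float = 0.02,
        self_transition: float = 0.99,
        max_iter: int = 100,
        tol: float = 1e-6,
    ) -> None:
        self.p_open_init = p_open_init
        self.p_closed_init = p_closed_init
        self.self_transition = self_transition
        self.max_iter = max_iter
        self.tol = tol

    def _sequences(self, table: pd.DataFrame):
        for _, sub in table.groupby("chrom", sort=True):
            sub = sub.sort_values("pos")
            yield (
                sub["pos"].to_numpy(),
                sub["meth"].to_numpy(dtype=np.float64),
                sub["total"].to_numpy(dtype=np.float64),
            )

    def fit(self, table: pd.DataFrame) -> "BinomialHmm":
        """Fit by Baum-Welch on a GCH site table (columns chrom, pos, meth,
        total; one row per site)."""
        seqs = [(m, t) for _, m, t in self._sequences(table)]
        if sum(len(m) for m, _ in seqs) < 10:
            raise ValueError("need at least 10 GCH sites to fit")
        if all((t == 0).all() for _, t in seqs):
            raise ValueError("all sites have zero coverage")
        p = np.array([self.p_open_init, self.p_closed_init])
        st = self.self_transition
        A = np.array([[st, 1 - st], [1 - st, st]])
        pi = np.array([0.5, 0.5])
        history: list[float] = []
        for _ in range(self.max_iter):
            ll = 0.0
            g0 = np.zeros(2)
            gm = np.zeros(2)
            gt = np.zeros(2)
            xi = np.zeros((2, 2))
            for meth, total in seqs:
                sll, sg0, _, sgm, sgt, sxi = _hmm.estep(meth, total, p[0], p[1], A, pi)
                ll += sll
                g0 += sg0
                gm += sgm
                gt += sgt
                xi += sxi
            if history and ll < history[-1] - 1e-6 * max(1.0, abs(history[-1])):
                raise RuntimeError("Baum-Welch log-likelihood decreased")
            converged = bool(history) and ll - history[-1] < self.tol
            history.append(ll)
            if converged:
                break
            p = np.clip(np.where(gt > 0, gm / np.where(gt > 0, gt, 1.0), p), 1e-6, 1 - 1e-6)
            rows = xi.sum(axis=1)
            A = np.where(rows[:, None] > 0, xi / np.where(rows[:, None] > 0, rows[:, None], 1.0), A)
            A = np.clip(A, 1e-9, None)
            A /= A.sum(axis=1, keepdims=True)
            pi = np.clip(g0 / g0.sum(), 1e-9, None)
            pi /= pi.sum()
        if p[0] < p[1]:  # canonicalise: state 0 = open
            p = p[::-1]
            A = A[::-1, ::-1]
            pi = pi[::-1]
        self.p_open_ = float(p[0])
        self.p_closed_ = float(p[1])
        self.transmat_ = A
        self.startprob_ = pi
        self.loglik_history_ = np.array(history)
        self.n_iter_ = len(history)
        return self

    def _params(self):
        return (
            self.p_open_,
            max(self.p_closed_, 1e-9),
            self.transmat_,
            self.startprob_,
        )

    def score(self, table: pd.DataFrame) -> float:
        """Total forward log-likelihood across chromosomes."""
        p0, p1, A, pi = self._params()
        return float(
            sum(
                _hmm.forward_loglik(m, t, p0, p1, A, pi)
                for _, m, t in self._sequences(table)
            )
        )

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Viterbi state path (0 = open, 1 = closed), in table order per
        chromosome (chromosomes sorted)."""
        p0, p1, A, pi = self._params()
        return np.concatenate(
            [
                _hmm.viterbi(m, t, p0, p1, A, pi)
                for _, m, t in self._sequences(table)
            ]
        )

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Posterior state probabilities per site (columns open, closed)."""
        p0, p1, A, pi = self._params()
        return np.vstack(
            [
                _hmm.posteriors(m, t, p0, p1, A, pi)
                for _, m, t in self._sequences(table)
            ]
        )


def segment(
    gch_table: pd.DataFrame, hmm: BinomialHmm, decode: str = "viterbi"
) -> tuple[RegionSet, RegionSet]:
    """Split the GCH landscape into putative NDRs and background.

    Maximal runs of open-state sites become putative NDRs spanning the first
    to last site of the run (end exclusive = last + 1); the complementary
    runs form the background set.
    """
    ndrs: list[GenomicRegion] = []
    background: list[GenomicRegion] = []
    p0, p1, A, pi = hmm._params()
    for chrom, sub in gch_table.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy(dtype=np.float64)
        total = sub["total"].to_numpy(dtype=np.float64)
        if decode == "viterbi":
            states = _hmm.viterbi(meth, total, p0, p1, A, pi)
        elif decode == "posterior":
            states = (_hmm.posteriors(meth, total, p0, p1, A, pi)[:, 0] < 0.5).astype(int)
        else:
            raise ValueError(f"unknown decode mode {decode!r}")
        open_state = states == 0
        i = 0
        n = len(pos)
        while i < n:
            j = i + 1
            while j < n and open_state[j] == open_state[i]:
                j += 1
            region = GenomicRegion(chrom, int(pos[i]), int(pos[j - 1]) + 1,
                                   {"n_gch": j - i})
            (ndrs if open_state[i] else background).append(region)
            i = j
    return RegionSet(ndrs), RegionSet(background)


def fisher_greater_pvalues(
    a_meth: np.ndarray, a_unmeth: np.ndarray, b_meth: np.ndarray, b_unmeth: np.ndarray
) -> np.ndarray:
    """One-sided Fisher's exact p (first row's methylation rate greater) for
    2x2 tables [[a_meth, a_unmeth], [b_meth, b_unmeth]], vectorised.

    Exact hypergeometric upper tail: P(X >= a_meth) with X ~
    Hypergeom(M = all observations, K = all methylated, n = row-1 total).
    """
    a_meth = np.asarray(a_meth, dtype=np.int64)
    a_unmeth = np.asarray(a_unmeth, dtype=np.int64)
    b_meth = np.asarray(b_meth, dtype=np.int64)
    b_unmeth = np.asarray(b_unmeth, dtype=np.int64)
    M = a_meth + a_unmeth + b_meth + b_unmeth
    K = a_meth + b_meth
    n = a_meth + a_unmeth
    return stats.hypergeom.sf(a_meth - 1, M, K, n)


def fisher_flank_test(
    ndr: GenomicRegion,
    gch_table: pd.DataFrame,
    flank_bp: int = 1000,
    left_bound: int = 0,
    right_bound: Optional[int] = None,
) -> Optional[tuple[float, tuple[int, int, int, int]]]:
    """Contrast a putative NDR against its flanking background.

    Each flank spans ``min(NDR length, flank_bp)`` bp of background
    territory, clipped at ``left_bound``/``right_bound`` (neighbouring NDR
    edges or contig ends). Returns ``(p, (inside_meth, inside_total,
    flank_meth, flank_total))`` or None when the test is undefined (no GCH
    observations inside or in either flank).
    """
    w = min(ndr.length, flank_bp)
    sub = gch_table[gch_table["chrom"] == ndr.chrom]
    pos = sub["pos"].to_numpy()
    meth = sub["meth"].to_numpy()
    total = sub["total"].to_numpy()
    inside = (pos >= ndr.start) & (pos < ndr.end)
    lf_start = max(left_bound, ndr.start - w)
    rf_end = ndr.end + w if right_bound is None else min(right_bound, ndr.end + w)
    flank = ((pos >= lf_start) & (pos < ndr.start)) | ((pos >= ndr.end) & (pos < rf_end))
    im, it = int(meth[inside].sum()), int(total[inside].sum())
    fm, ft = int(meth[flank].sum()), int(total[flank].sum())
    if it == 0 or ft == 0:
        return None
    p = float(fisher_greater_pvalues(im, it - im, fm, ft - fm))
    return p, (im, it, fm, ft)


def shuffle_gch(
    gch_table: pd.DataFrame, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Permute the (meth, total) pairs uniformly across GCH positions, per
    chromosome. Positions stay fixed; the value multiset is preserved
    exactly, destroying only the spatial arrangement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = gch_table.copy()
    for chrom in out["chrom"].unique():
        idx = out.index[out["chrom"] == chrom].to_numpy()
        perm = rng.permutation(len(idx))
        out.loc[idx, ["meth", "total"]] = (
            out.loc[idx[perm], ["meth", "total"]].to_numpy()
        )
    return out


def compute_efdr(
    observed_pvalues: Sequence[float],
    null_pvalues: Sequence[float],
    n_shuffles: int,
) -> np.ndarray:
    """Empirical FDR per observed p-value.

    ``eFDR(p) = [(#null p' <= p) / n_shuffles] / max(1, #observed p'' <= p)``
    with the null pooled over all shuffles, clipped to [0, 1] and made
    monotone non-decreasing in p.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    obs = np.asarray(observed_pvalues, dtype=float)
    null = np.sort(np.asarray(null_pvalues, dtype=float))
    obs_sorted = np.sort(obs)
    n_null_le = np.searchsorted(null, obs, side="right")
    n_obs_le = np.searchsorted(obs_sorted, obs, side="right")
    efdr = (n_null_le / n_shuffles) / np.maximum(1, n_obs_le)
    efdr = np.clip(efdr, 0.0, 1.0)
    order = np.argsort(obs, kind="mergesort")
    efdr[order] = np.maximum.accumulate(efdr[order])
    return efdr


def _candidate_pvalues(
    gch_table: pd.DataFrame,
    hmm: BinomialHmm,
    flank_bp: int,
    min_sites: int,
    decode: str = "viterbi",
) -> list[NdrCall]:
    """Segment + Fisher on one table; returns candidates with fisher_p."""
    ndrs, _ = segment(gch_table, hmm, decode=decode)
    calls: list[NdrCall] = []
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in ndrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    chrom_max = gch_table.groupby("chrom")["pos"].max().to_dict()
    for chrom, regions in by_chrom.items():
        regions.sort(key=lambda r: r.start)
        for k, r in enumerate(regions):
            if r.attrs.get("n_gch", 0) < min_sites:
                continue
            left_bound = regions[k - 1].end if k > 0 else 0
            right_bound = (
                regions[k + 1].start if k + 1 < len(regions) else int(chrom_max[chrom]) + 1
            )
            res = fisher_flank_test(r, gch_table, flank_bp, left_bound, right_bound)
            if res is None:
                logger.info("dropping NDR %s:%d-%d: no flanking GCH observations",
                            r.chrom, r.start, r.end)
                continue
            p, (im, it, fm, ft) = res
            calls.append(NdrCall(r, r.attrs["n_gch"], im, it, fm, ft, p))
    return calls


def call_ndrs(
    gch_table: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    n_shuffles: int = 5,
    min_sites: int = 4,
    seed: int = 0,
    hmm: Optional[BinomialHmm] = None,
    decode: str = "viterbi",
) -> tuple[list[NdrCall], list[NdrCall]]:
    """Full NDR calling: fit -> segment -> Fisher -> shuffle null -> eFDR.

    ``gch_table`` may contain any contexts; GCG rows are removed and only
    GCH rows are used. Candidates need at least ``min_sites`` GCH sites (a
    sub-nucleosome-width segment is not a credible NDR). Returns
    ``(kept, candidates)`` where ``kept`` are candidates with
    eFDR < ``efdr_cutoff``.
    """
    config = config or PipelineConfig()
    if "sample_id" in gch_table.columns and gch_table["sample_id"].nunique() > 1:
        raise ValueError(
            "NDR calling is per sample; filter the table to one sample_id first"
        )
    if "context" in gch_table.columns and gch_table["context"].notna().any():
        gch = gch_table[gch_table["context"] == "GCH"]
    else:
        gch = gch_table
    gch = gch[gch["total"] > 0].reset_index(drop=True)
    if hmm is None:
        hmm = BinomialHmm().fit(gch)
    candidates = _candidate_pvalues(gch, hmm, config.flank_bp, min_sites, decode)
    rng = np.random.default_rng(seed)
    null_p: list[float] = []
    for _ in range(n_shuffles):
        shuffled = shuffle_gch(gch, rng)
        null_p.extend(
            c.fisher_p
            for c in _candidate_pvalues(shuffled, hmm, config.flank_bp, min_sites, decode)
        )
    if candidates:
        efdr = compute_efdr([c.fisher_p for c in candidates], null_p, n_shuffles)
        for c, e in zip(candidates, efdr):
            c.efdr = float(e)
    kept = [c for c in candidates if c.efdr < config.efdr_cutoff]
    return kept, candidates


class NdrCaller(BaseEstimator):
    """NOMe-seq NDR caller (scikit-learn-style estimator).

    ``fit`` runs the full pipeline on a GCH site table; fitted attributes
    are ``hmm_`` (the fitted :class:`BinomialHmm`), ``candidates_`` (all
    putative NDRs with Fisher p and eFDR) and ``calls_`` (those passing
    eFDR < ``efdr_cutoff``).
    """

    def __init__(
        self,
        efdr_cutoff: float = 0.01,
        n_shuffles: int = 5,
        flank_bp: int = 1000,
        min_sites: int = 4,
        seed: int = 0,
        decode: str = "viterbi",
    ) -> None:
        self.efdr_cutoff = efdr_cutoff
        self.n_shuffles = n_shuffles
        self.flank_bp = flank_bp
        self.min_sites = min_sites
        self.seed = seed
        self.decode = decode

    def fit(self, gch_table: pd.DataFrame) -> "NdrCaller":
        config = PipelineConfig(efdr_cutoff=self.efdr_cutoff, flank_bp=self.flank_bp)
        if "sample_id" in gch_table.columns and gch_table["sample_id"].nunique() > 1:
            raise ValueError(
                "NDR calling is per sample; filter the table to one sample_id first"
            )
        if "context" in gch_table.columns and gch_table["context"].notna().any():
            gch = gch_table[gch_table["context"] == "GCH"]
        else:
            gch = gch_table
        gch = gch[gch["total"] > 0].reset_index(drop=True)
        self.hmm_ = BinomialHmm().fit(gch)
        self.calls_, self.candidates_ = call_ndrs(
            gch,
            config,
            n_shuffles=self.n_shuffles,
            min_sites=self.min_sites,
            seed=self.seed,
            hmm=self.hmm_,
            decode=self.decode,
        )
        return self

    @property
    def regions_(self) -> RegionSet:
        return RegionSet(
            GenomicRegion(
                c.chrom, c.start, c.end,
                {"name": f"NDR{i + 1}", "n_gch": c.n_gch,
                 "fisher_p": c.fisher_p, "efdr": c.efdr},
            )
            for i, c in enumerate(self.calls_)
        )


def summarize_peaks(peaks: RegionSet) -> tuple[int, int]:
    """(count, covered bp) of the merged peak set."""
    merged = peaks.merged() if len(peaks) else peaks
    return len(merged), sum(r.length for r in merged)
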