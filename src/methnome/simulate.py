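"""Synthetic data with the statistical structure the pipeline assumes.

Generators are pure functions of their parameters and seed. They emulate a
two-cell-type (monocyte -> macrophage), two-donor design: a mostly highly
methylated CpG landscape with planted differentially methylated regions
(DMRs), NOMe-seq GCH accessibility with planted nucleosome-depleted regions
(NDRs), paired BS/oxBS counts with planted 5mC/5hmC fractions, a TFBS track
enriched at planted DMRs and three-class histone-signature matrices.

The ground truth of every planted feature is returned as a
:class:`SyntheticTruth` so downstream recovery tests never need to re-derive
it from the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .meth_io import SITE_COLUMNS, catalog_cytosines, make_site_table
from .regions import GenomicRegion, RegionSet

CELL_TYPES = ("monocyte", "macrophage")

HISTONE_MARKS = (
    "H3K27ac",
    "H3K4me1",
    "H3K4me3",
    "H3K36me3",
    "H3K27me3",
    "H3K9me3",
)

# Per-class mean log2(ChIP/input) body level by (mark, cell type).
# Class 1: gains the active-enhancer signature (H3K27ac/H3K4me1/H3K4me3),
# loses H3K27me3. Class 2: the same gains on an actively transcribed
# background (constitutive H3K36me3). Class 3: constitutively active with a
# reduced H3K4me1 signal in macrophages.
CLASS_SIGNATURES: dict[int, dict[str, tuple[float, float]]] = {
    1: {
        "H3K27ac": (0.0, 1.5),
        "H3K4me1": (0.2, 1.5),
        "H3K4me3": (0.0, 1.0),
        "H3K36me3": (0.0, 0.0),
        "H3K27me3": (1.0, 0.1),
        "H3K9me3": (0.0, 0.0),
    },
    2: {
        "H3K27ac": (0.0, 1.5),
        "H3K4me1": (0.2, 1.5),
        "H3K4me3": (0.0, 1.0),
        "H3K36me3": (1.2, 1.2),
        "H3K27me3": (0.0, 0.0),
        "H3K9me3": (0.0, 0.0),
    },
    3: {
        "H3K27ac": (1.5, 1.5),
        "H3K4me1": (1.5, 0.9),
        "H3K4me3": (1.2, 1.2),
        "H3K36me3": (0.0, 0.0),
        "H3K27me3": (0.0, 0.0),
        "H3K9me3": (0.0, 0.0),
    },
}


@dataclass
class SimulationParams:
    """Study-design parameters for the generators.

    The defaults mirror the emulated design: two donors per cell type, a
    highly methylated baseline (most planted DMRs lose methylation during
    differentiation, 96% loss vs 4% gain), accessibility emission rates of
    0.5 (open) vs 0.05 (closed) GCH methylation, and a symmetric bisulfite
    conversion error of 0.005 (within a >= 95% conversion requirement).
    """

    genome_length: int = 200_000
    gc_content: float = 0.42
    n_samples: int = 2
    coverage: float = 30.0
    baseline_meth: float = 0.8
    dmr_delta: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    n_dmrs: int = 20
    dmr_cpg_range: tuple[int, int] = (6, 12)
    loss_fraction: float = 0.96
    ndr_p_open: float = 0.5
    ndr_p_closed: float = 0.05
    ndr_length: int = 500
    n_ndrs: tuple[int, int] = (10, 20)  # (monocyte, macrophage)
    nome_coverage: float = 20.0
    conversion_error: float = 0.005
    donor_effect: float = 0.02
    tfbs_enrichment: float = 0.9
    tfbs_background_per_mb: float = 50.0
    tfbs_length: int = 15
    chip_noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "baseline_meth", "ndr_p_open", "ndr_p_closed",
                     "conversion_error", "loss_fraction", "tfbs_enrichment"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gc_content in (0.0, 1.0):
            raise ValueError("gc_content must be strictly between 0 and 1")
        if not self.ndr_p_open > self.ndr_p_closed:
            raise ValueError("ndr_p_open must exceed ndr_p_closed")


@dataclass
class SyntheticTruth:
    """Ground truth of all planted features."""

    planted_dmrs: RegionSet = field(default_factory=RegionSet)
    planted_ndrs: dict[str, RegionSet] = field(default_factory=dict)
    planted_5hmc: Optional[pd.DataFrame] = None
    tfbs_track: RegionSet = field(default_factory=RegionSet)
    cluster_labels: Optional[np.ndarray] = None
    sample_groups: dict[str, list[str]] = field(default_factory=dict)


def simulate_genome(params: SimulationParams) -> tuple[dict[str, str], pd.DataFrame]:
    """Random i.i.d. sequence at the requested GC content plus a catalog of
    every cytosine with its trinucleotide context."""
    if params.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(params.rng_seed)
    g = params.gc_content
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G T
    bases = rng.choice(np.array(["A", "C", "G", "T"]), size=params.genome_length, p=probs)
    genome = {"chr1": "".join(bases)}
    catalog = catalog_cytosines(genome)
    return genome, catalog


def _cpg_positions(catalog: pd.DataFrame, chrom: str = "chr1") -> np.ndarray:
    """Plus-strand positions of CpG cytosines (HCG or GCG context)."""
    mask = (
        (catalog["chrom"] == chrom)
        & (catalog["strand"] == "+")
        & catalog["context"].isin(["HCG", "GCG"])
    )
    return np.sort(catalog.loc[mask, "pos"].to_numpy())


def _observed_counts(
    rng: np.random.Generator, fraction: np.ndarray, coverage: float, err: float
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth and binomial methylated counts with a symmetric
    conversion-error channel."""
    total = rng.poisson(coverage, size=fraction.shape)
    p = fraction * (1 - err) + (1 - fraction) * err
    meth = rng.binomial(total, p)
    return meth, total


def _plant_blocks(
    rng: np.random.Generator,
    positions: np.ndarray,
    n_blocks: int,
    cpg_range: tuple[int, int],
    min_separation: int = 3000,
    min_span_bp: int = 85,
) -> list[tuple[int, int, int]]:
    """Pick non-adjacent runs of consecutive CpGs; returns (i0, i1, n) index
    ranges into ``positions`` (inclusive start, exclusive end).

    Blocks narrower than ``min_span_bp`` are rejected: real DMRs rarely
    span less than ~85 bp, and a sub-nucleosome block is not a realistic
    regulatory unit.
    """
    blocks: list[tuple[int, int, int]] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(blocks) < n_blocks and attempts < 50_000:
        attempts += 1
        k = int(rng.integers(cpg_range[0], cpg_range[1] + 1))
        i0 = int(rng.integers(0, len(positions) - k))
        start, end = int(positions[i0]), int(positions[i0 + k - 1]) + 1
        if end - start < min_span_bp:
            continue
        if any(start - min_separation < e and s < end + min_separation for s, e in taken):
            continue
        taken.append((start, end))
        blocks.append((i0, i0 + k, k))
    if len(blocks) < n_blocks:
        raise RuntimeError("could not place the requested planted blocks")
    return sorted(blocks)


def simulate_methylomes(
    genome: dict[str, str],
    catalog: pd.DataFrame,
    params: SimulationParams,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """WGBS-style CpG count tables for two cell types x ``n_samples`` donors
    with planted DMRs.

    Inside a planted loss DMR (the default 96% of regions) with difference
    ``d`` the monocyte fraction is ``baseline`` and the macrophage fraction
    ``baseline - d``; a gain DMR starts from the hypomethylated baseline
    ``1 - baseline`` and rises by ``d`` (a saturated CpG cannot gain).
    Fractions are clipped to [0, 1] with a warning. Counts are
    Binomial(Poisson depth, f*(1-err) + (1-f)*err).
    """
    rng = np.random.default_rng(params.rng_seed + 1)
    chrom = "chr1"
    positions = _cpg_positions(catalog, chrom)
    blocks = _plant_blocks(rng, positions, params.n_dmrs, params.dmr_cpg_range)

    base = np.full(len(positions), params.baseline_meth)
    mono = base.copy()
    mac = base.copy()
    dmrs = []
    for bi, (i0, i1, k) in enumerate(blocks):
        d = float(rng.choice(np.asarray(params.dmr_delta)))
        loss = bool(rng.random() < params.loss_fraction)
        lo, hi = int(positions[i0]), int(positions[i1 - 1]) + 1
        if loss:
            start_frac = params.baseline_meth
            target = start_frac - d
        else:
            # regions gaining methylation start from the hypomethylated
            # baseline (a saturated CpG cannot gain)
            start_frac = 1.0 - params.baseline_meth
            target = start_frac + d
        clipped = float(np.clip(target, 0.0, 1.0))
        if clipped != target:
            warnings.warn(
                f"DMR{bi + 1}: delta {d} pushes fraction outside [0, 1]; clipped"
            )
        mono[i0:i1] = start_frac
        mac[i0:i1] = clipped
        dmrs.append(
            GenomicRegion(
                chrom, lo, hi,
                {"name": f"DMR{bi + 1}", "delta": d,
                 "effective_delta": abs(clipped - start_frac), "n_cpgs": k,
                 "direction": "loss" if loss else "gain"},
            )
        )

    frames = []
    groups: dict[str, list[str]] = {ct: [] for ct in CELL_TYPES}
    for ct, truth_frac in zip(CELL_TYPES, (mono, mac)):
        for donor in range(params.n_samples):
            sample_id = f"{ct}_d{donor + 1}"
            groups[ct].append(sample_id)
            shift = params.donor_effect * (donor - (params.n_samples - 1) / 2)
            frac = np.clip(truth_frac + shift, 0.0, 1.0)
            meth, total = _observed_counts(rng, frac, params.coverage, params.conversion_error)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": positions,
                        "strand": "+",
                        "context": "HCG",
                        "sample_id": sample_id,
                        "meth": meth,
                        "total": total,
                    }
                )
            )
    table = make_site_table(pd.concat(frames, ignore_index=True))
    truth = SyntheticTruth(planted_dmrs=RegionSet(dmrs), sample_groups=groups)
    return table, truth


def _plant_intervals(
    rng: np.random.Generator,
    genome_length: int,
    n: int,
    length: int,
    min_separation: int = 2500,
    avoid: Sequence[tuple[int, int]] = (),
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = list(avoid)
    out: list[tuple[int, int]] = []
    attempts = 0
    while len(out) < n and attempts < 50_000:
        attempts += 1
        start = int(rng.integers(1000, genome_length - length - 1000))
        end = start + length
        if any(start - min_separation < e and s < end + min_separation for s, e in placed):
            continue
        placed.append((start, end))
        out.append((start, end))
    if len(out) < n:
        raise RuntimeError("could not place the requested intervals")
    return sorted(out)


def simulate_nome(
    genome: dict[str, str],
    catalog: pd.DataFrame,
    params: SimulationParams,
    dmr_truth: Optional[SyntheticTruth] = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """NOMe-seq count tables (one sample per cell type) with planted NDRs.

    GCH sites inside a planted NDR emit at ``ndr_p_open``, elsewhere at
    ``ndr_p_closed``. HCG (endogenous CpG) rows are co-generated at the
    baseline methylation -- demethylated inside any planted DMRs passed via
    ``dmr_truth`` so DMR/NDR co-location can be planted -- GCG rows are
    generated but flagged by their context, and HCH rows emit at the
    conversion error rate.
    """
    rng = np.random.default_rng(params.rng_seed + 2)
    chrom = "chr1"
    cat = catalog[catalog["chrom"] == chrom]
    frames = []
    truth_ndrs: dict[str, RegionSet] = {}
    avoid: list[tuple[int, int]] = []
    planted: dict[str, list[tuple[int, int]]] = {}
    for ct, n_ndr in zip(CELL_TYPES, params.n_ndrs):
        planted[ct] = _plant_intervals(
            rng, len(genome[chrom]), n_ndr, params.ndr_length, avoid=avoid
        )
        avoid += planted[ct]
        truth_ndrs[ct] = RegionSet(
            GenomicRegion(chrom, s, e, {"name": f"{ct}_NDR{i + 1}", "p_open": params.ndr_p_open})
            for i, (s, e) in enumerate(planted[ct])
        )

    dmr_set = dmr_truth.planted_dmrs if dmr_truth is not None else RegionSet()

    for ct in CELL_TYPES:
        pos = cat["pos"].to_numpy()
        ctx = cat["context"].to_numpy()
        strand = cat["strand"].to_numpy()
        frac = np.empty(len(pos))
        in_ndr = np.zeros(len(pos), dtype=bool)
        for s, e in planted[ct]:
            in_ndr |= (pos >= s) & (pos < e)
        gch = ctx == "GCH"
        frac[gch] = np.where(in_ndr[gch], params.ndr_p_open, params.ndr_p_closed)
        hcg = ctx == "HCG"
        cpg_frac = np.full(int(hcg.sum()), params.baseline_meth)
        if len(dmr_set):
            hpos = pos[hcg]
            for r in dmr_set:
                d = r.attrs.get("effective_delta", r.attrs.get("delta", 0.0))
                loss = r.attrs.get("direction", "loss") == "loss"
                inside = (hpos >= r.start) & (hpos < r.end)
                start_frac = params.baseline_meth if loss else 1.0 - params.baseline_meth
                if ct == "macrophage":
                    cpg_frac[inside] = np.clip(
                        start_frac + (-d if loss else d), 0, 1
                    )
                else:
                    cpg_frac[inside] = start_frac
        frac[hcg] = cpg_frac
        # GCG is ambiguous between endogenous and enzymatic methylation;
        # emit a mixture-ish rate, it is excluded downstream anyway
        gcg = ctx == "GCG"
        frac[gcg] = np.where(in_ndr[gcg], params.ndr_p_open, params.baseline_meth)
        hch = ctx == "HCH"
        frac[hch] = 0.0
        meth, total = _observed_counts(rng, frac, params.nome_coverage, params.conversion_error)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": ctx,
                    "sample_id": ct,
                    "meth": meth,
                    "total": total,
                }
            )
        )
    table = make_site_table(pd.concat(frames, ignore_index=True))
    truth = SyntheticTruth(planted_ndrs=truth_ndrs,
                           planted_dmrs=dmr_set,
                           sample_groups={ct: [ct] for ct in CELL_TYPES})
    return table, truth


def simulate_oxbs(
    params: SimulationParams,
    n_sites: int = 100,
    depth: float = 100.0,
    frac_5mc: float = 0.6,
    frac_5hmc: float = 0.2,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Paired BS/oxBS counts at planted (5mC, 5hmC) fractions.

    BS reads both 5mC and 5hmC as cytosine, oxBS only 5mC:
    ``bs_meth ~ Binomial(n, 5mC + 5hmC)``, ``oxbs_meth ~ Binomial(n, 5mC)``.
    """
    if frac_5mc + frac_5hmc > 1:
        raise ValueError("5mC + 5hmC must be <= 1")
    rng = np.random.default_rng(params.rng_seed + 3 if seed is None else seed)
    pos = np.arange(n_sites) * 50 + 100
    bs_total = rng.poisson(depth, n_sites)
    ox_total = rng.poisson(depth, n_sites)
    bs_meth = rng.binomial(bs_total, frac_5mc + frac_5hmc)
    ox_meth = rng.binomial(ox_total, frac_5mc)
    pairs = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "bs_meth": bs_meth,
            "bs_total": bs_total,
            "oxbs_meth": ox_meth,
            "oxbs_total": ox_total,
        }
    )
    truth5 = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "frac_5mc": frac_5mc, "frac_5hmc": frac_5hmc}
    )
    return pairs, SyntheticTruth(planted_5hmc=truth5)


def simulate_tfbs_track(
    truth: SyntheticTruth,
    params: SimulationParams,
    genome_length: Optional[int] = None,
) -> RegionSet:
    """A TFBS track in which a configurable fraction of planted DMRs contain
    at least one site, plus uniform background sites."""
    rng = np.random.default_rng(params.rng_seed + 4)
    genome_length = genome_length or params.genome_length
    tfbs: list[GenomicRegion] = []
    for r in truth.planted_dmrs:
        if rng.random() < params.tfbs_enrichment:
            lo = r.start if r.length <= params.tfbs_length else int(
                rng.integers(r.start, r.end - params.tfbs_length)
            )
            tfbs.append(GenomicRegion(r.chrom, lo, lo + params.tfbs_length))
    n_bg = rng.poisson(params.tfbs_background_per_mb * genome_length / 1e6)
    for _ in range(n_bg):
        s = int(rng.integers(0, genome_length - params.tfbs_length))
        tfbs.append(GenomicRegion("chr1", s, s + params.tfbs_length))
    out = RegionSet(tfbs).sorted()
    truth.tfbs_track = out
    return out


def simulate_chip_matrix(
    params: SimulationParams,
    n_regions: int = 90,
    n_bins: int = 120,
    class_probs: Sequence[float] = (0.4, 0.3, 0.3),
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Binned log2(ChIP/input) matrices for six marks x two cell types with
    three planted signature classes plus Gaussian noise.

    Returns a DataFrame with MultiIndex columns ``(mark, cell_type, bin)``
    (``n_bins`` bins per mark per cell type: 40 left-flank, 40 body, 40
    right-flank by default) and the true class label (1-3) per region.
    """
    rng = np.random.default_rng(params.rng_seed + 5 if seed is None else seed)
    labels = rng.choice([1, 2, 3], size=n_regions, p=np.asarray(class_probs))
    third = n_bins // 3
    body = np.zeros(n_bins)
    body[third: 2 * third] = 1.0
    flank = np.zeros(n_bins)
    flank[:third] = 0.3
    flank[2 * third:] = 0.3
    shape = body + flank  # flanks carry attenuated signal

    cols = pd.MultiIndex.from_product(
        [HISTONE_MARKS, CELL_TYPES, range(n_bins)], names=["mark", "cell_type", "bin"]
    )
    values = np.empty((n_regions, len(cols)))
    j = 0
    for mark in HISTONE_MARKS:
        for ci, ct in enumerate(CELL_TYPES):
            level = np.array(
                [CLASS_SIGNATURES[lab][mark][ci] for lab in labels]
            )[:, None]
            block = level * shape[None, :]
            block = block + rng.normal(0.0, params.chip_noise_sd, block.shape)
            values[:, j: j + n_bins] = block
            j += n_bins
    matrix = pd.DataFrame(values, columns=cols)
    return matrix, labels
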