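"""Methylation-count tables, cytosine context classification and file I/O.

The central container is a "site table": a :class:`pandas.DataFrame` with
columns ``chrom, pos, strand, context, sample_id, meth, total`` where ``pos``
is the 0-based coordinate of the cytosine, ``context`` is one of the four
trinucleotide classes ``HCG`` (endogenous CpG readout), ``GCH`` (NOMe-seq
accessibility readout), ``GCG`` (ambiguous; flagged and excluded downstream)
and ``HCH`` (bisulfite-conversion control; H = A/C/T), and ``meth``/``total``
are counts of methylated and total passing base calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONTEXTS = ("HCG", "GCH", "GCG", "HCH")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "sample_id", "meth", "total"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ContextError(ValueError):
    """Raised when a position is not a cytosine on the requested strand or
    lacks a flanking neighbour on the contig."""


@dataclass
class PipelineConfig:
    """Analysis parameters shared across pipeline stages.

    Defaults follow the study design this pipeline reproduces: reads below
    mapping quality 30 are excluded and bases below base quality 17 ignored;
    DMRs require a methylation difference >= 0.3 over >= 4 CpGs at a per-CpG
    q-value <= 1e-4; NDRs are kept at empirical FDR < 0.01; histone signatures
    are clustered with k-means (k = 3) on 25 bp bins over regions plus 1 kb
    flanks; cluster-wise paired tests use Bonferroni-corrected alpha 0.001.
    """

    mapq_min: int = 30
    baseq_min: int = 17
    dmr_min_diff: float = 0.3
    dmr_min_cpgs: int = 4
    dmr_q_cutoff: float = 1e-4
    efdr_cutoff: float = 0.01
    n_permutations: int = 1_000_000
    kmeans_k: int = 3
    bin_size_bp: int = 25
    flank_bp: int = 1000
    alpha_bonferroni: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dmr_min_diff <= 1):
            raise ValueError("dmr_min_diff must be in [0, 1]")
        if self.dmr_min_cpgs < 1:
            raise ValueError("dmr_min_cpgs must be >= 1")
        for name in ("dmr_q_cutoff", "efdr_cutoff", "alpha_bonferroni"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.mapq_min < 0 or self.baseq_min < 0:
            raise ValueError("quality thresholds must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def classify_context(
    genome: Mapping[str, str], chrom: str, pos: int, strand: str = "+"
) -> str:
    """Classify the trinucleotide context of a cytosine.

    On the minus strand the cytosine appears as a reference ``G`` and its
    5'/3' neighbours are the complements of the reference bases at
    ``pos + 1`` / ``pos - 1``.

    Raises
    ------
    ContextError
        If the reference base at ``pos`` is not a cytosine on ``strand`` or
        the position lies at a contig edge (no 5' or 3' neighbour).
    """
    seq = genome[chrom]
    if pos < 0 or pos >= len(seq):
        raise ContextError(f"{chrom}:{pos} outside contig")
    base = seq[pos].upper()
    if strand == "+":
        if base != "C":
            raise ContextError(f"{chrom}:{pos}+ is {base}, not C")
        if pos == 0 or pos == len(seq) - 1:
            raise ContextError(f"{chrom}:{pos} at contig edge")
        prev = seq[pos - 1].upper()
        nxt = seq[pos + 1].upper()
    elif strand == "-":
        if base != "G":
            raise ContextError(f"{chrom}:{pos}- is {base}, not C on minus strand")
        if pos == 0 or pos == len(seq) - 1:
            raise ContextError(f"{chrom}:{pos} at contig edge")
        prev = _COMPLEMENT.get(seq[pos + 1].upper(), "N")
        nxt = _COMPLEMENT.get(seq[pos - 1].upper(), "N")
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    # H = A/C/T; any non-G (including ambiguity codes) counts as H
    five_g = prev == "G"
    three_g = nxt == "G"
    if three_g:
        return "GCG" if five_g else "HCG"
    return "GCH" if five_g else "HCH"


def catalog_cytosines(genome: Mapping[str, str]) -> pd.DataFrame:
    """Vectorised scan of every cytosine (both strands) with its context.

    Returns a DataFrame with columns ``chrom, pos, strand, context``, sorted
    by position within chromosome. Contig-edge cytosines (no neighbour) are
    omitted.
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        n = len(arr)
        if n < 3:
            continue
        inner = np.arange(1, n - 1)
        # plus strand: reference C, neighbours read left to right
        plus = inner[is_c[inner]]
        p5 = is_g[plus - 1]
        p3 = is_g[plus + 1]
        plus_ctx = np.where(p3, np.where(p5, "GCG", "HCG"), np.where(p5, "GCH", "HCH"))
        # minus strand: reference G; 5' neighbour is complement of pos+1
        minus = inner[is_g[inner]]
        m5 = is_c[minus + 1]  # complement(C) == G neighbour on minus strand
        m3 = is_c[minus - 1]
        minus_ctx = np.where(m3, np.where(m5, "GCG", "HCG"), np.where(m5, "GCH", "HCH"))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([plus, minus]),
                    "strand": np.repeat(["+", "-"], [len(plus), len(minus)]),
                    "context": np.concatenate([plus_ctx, minus_ctx]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def make_site_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a site table (see module docstring)."""
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    df = df[SITE_COLUMNS].copy()
    if (df["meth"] < 0).any() or (df["meth"] > df["total"]).any():
        raise ValueError("site table requires 0 <= meth <= total")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"unknown contexts: {sorted(df.loc[bad, 'context'].unique())}")
    if df.duplicated(["chrom", "pos", "strand", "sample_id"]).any():
        raise ValueError("duplicate (chrom, pos, strand, sample_id) rows")
    return df.sort_values(["sample_id", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def call_methylation(
    records: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    genome: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Quality-filtered methylation calling from per-base pileup records.

    ``records`` columns: ``chrom, pos, observed_base, mapping_quality,
    base_quality, sample_id`` and optionally ``strand`` (default ``+``).
    A base contributes only when ``mapping_quality >= mapq_min`` and
    ``base_quality >= baseq_min`` (thresholds are strict "lower than"
    rejections, so the defaults 30 and 17 themselves pass); ``meth`` counts
    retained ``C`` observations and ``total`` retained ``C`` or ``T``.

    When a ``genome`` is given, each site's context is classified against the
    reference; otherwise the context column is left empty.
    """
    config = config or PipelineConfig()
    if records.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    rec = records.copy()
    if "strand" not in rec.columns:
        rec["strand"] = "+"
    keep = (rec["mapping_quality"] >= config.mapq_min) & (
        rec["base_quality"] >= config.baseq_min
    )
    rec = rec[keep & rec["observed_base"].isin(["C", "T"])]
    if rec.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    grouped = (
        rec.assign(is_c=(rec["observed_base"] == "C").astype(int))
        .groupby(["chrom", "pos", "strand", "sample_id"], as_index=False)
        .agg(meth=("is_c", "sum"), total=("is_c", "size"))
    )
    if genome is not None:
        grouped["context"] = [
            classify_context(genome, c, p, s)
            for c, p, s in zip(grouped["chrom"], grouped["pos"], grouped["strand"])
        ]
    else:
        grouped["context"] = ""
    grouped = grouped[SITE_COLUMNS]
    return grouped.sort_values(
        ["sample_id", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)


def read_bedgraph_methylation(path) -> pd.DataFrame:
    """Read a bedGraph-like methylation TSV.

    Columns: ``chrom, start, end, meth, total, context`` and optionally
    ``strand`` and ``sample_id`` (7th/8th columns). ``end`` must equal
    ``start + 1``; counts must satisfy 0 <= meth <= total.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            try:
                start, end, meth, total = int(f[1]), int(f[2]), int(f[3]), int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if end != start + 1:
                raise ValueError(f"{path}:{lineno}: end must be start + 1")
            if not (0 <= meth <= total):
                raise ValueError(f"{path}:{lineno}: requires 0 <= meth <= total")
            strand = f[6] if len(f) > 6 else "+"
            sample = f[7] if len(f) > 7 else "sample"
            rows.append((f[0], start, strand, f[5], sample, meth, total))
    return make_site_table(pd.DataFrame(rows, columns=SITE_COLUMNS))


def write_bedgraph_methylation(table: pd.DataFrame, path) -> None:
    """Write a site table as a bedGraph-like TSV (lossless round-trip with
    :func:`read_bedgraph_methylation`)."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.meth}\t{row.total}\t"
                f"{row.context}\t{row.strand}\t{row.sample_id}\n"
            )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def methylation_fraction(table: pd.DataFrame) -> pd.Series:
    """Per-row methylated fraction (NaN where total == 0)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = table["meth"] / table["total"]
    return frac.where(table["total"] > 0)


def hch_conversion_summary(table: pd.DataFrame) -> float:
    """Mean methylated fraction at HCH (conversion-control) sites.

    A well-converted library has a value close to the conversion error rate.
    """
    hch = table[(table["context"] == "HCH") & (table["total"] > 0)]
    if hch.empty:
        return float("nan")
    return float(hch["meth"].sum() / hch["total"].sum())
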