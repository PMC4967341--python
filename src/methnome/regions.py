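"""Genomic intervals and interval sets.

All coordinates are 0-based half-open ([start, end)), i.e. BED semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass
class GenomicRegion:
    """A half-open genomic interval with optional annotations.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name. Must be non-empty.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must be greater than ``start``.
    attrs : dict, optional
        Free-form annotation (``name``, ``score``, ``direction``, ...).
    """

    chrom: str
    start: int
    end: int
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicRegion") -> float:
        """Smaller of the two overlap fractions (0 when disjoint)."""
        inter = self.intersection_length(other)
        if inter == 0:
            return 0.0
        return min(inter / self.length, inter / other.length)


class RegionSet:
    """A queryable collection of :class:`GenomicRegion`.

    Overlap queries are backed by per-chromosome interval trees built lazily.
    """

    def __init__(self, regions: Iterable[GenomicRegion] = ()) -> None:
        self.regions: list[GenomicRegion] = list(regions)
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def add(self, region: GenomicRegion) -> None:
        self.regions.append(region)
        self._trees = None

    def _build(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.regions:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicRegion]:
        tree = self._build().get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.overlap(start, end))]

    def any_overlap(self, region: GenomicRegion) -> bool:
        tree = self._build().get(region.chrom)
        return bool(tree is not None and tree.overlap(region.start, region.end))

    def merged(self) -> "RegionSet":
        """Union of all intervals (book-ended intervals are joined)."""
        out: list[GenomicRegion] = []
        by_chrom: dict[str, list[GenomicRegion]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom in sorted(by_chrom):
            rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
            cur_s, cur_e = rs[0].start, rs[0].end
            for r in rs[1:]:
                if r.start <= cur_e:
                    cur_e = max(cur_e, r.end)
                else:
                    out.append(GenomicRegion(chrom, cur_s, cur_e))
                    cur_s, cur_e = r.start, r.end
            out.append(GenomicRegion(chrom, cur_s, cur_e))
        return RegionSet(out)

    @property
    def total_bp(self) -> int:
        """Summed length of the merged intervals."""
        return sum(r.length for r in self.merged())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row = {"chrom": r.chrom, "start": r.start, "end": r.end}
            row.update(r.attrs)
            rows.append(row)
        return pd.DataFrame(rows)

    def sorted(self) -> "RegionSet":
        return RegionSet(
            sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        )


def read_bed(path) -> RegionSet:
    """Read BED3+ (optional name and score columns) into a :class:`RegionSet`."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            attrs: dict = {}
            if len(fields) > 3:
                attrs["name"] = fields[3]
            if len(fields) > 4:
                attrs["score"] = fields[4]
            if len(fields) > 5:
                attrs["strand"] = fields[5]
            regions.append(GenomicRegion(chrom, start, end, attrs))
    return RegionSet(regions)


def write_bed(regions: RegionSet, path, extra_attrs: Optional[list[str]] = None) -> None:
    """Write BED3+ with name/score/strand when present, then ``extra_attrs``."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fields = [r.chrom, str(r.start), str(r.end)]
            name = r.attrs.get("name", f"region{i + 1}")
            score = r.attrs.get("score", 0)
            strand = r.attrs.get("strand", ".")
            tail = [str(r.attrs.get(k, "")) for k in (extra_attrs or [])]
            if tail or "strand" in r.attrs or "score" in r.attrs or "name" in r.attrs:
                fields += [str(name), str(score), str(strand)] + tail
            fh.write("\t".join(fields) + "\n")


def reciprocal_overlap_recovery(
    truth: RegionSet, calls: RegionSet, min_fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask over ``truth``: recovered by >= one call at the given
    reciprocal-overlap fraction."""
    hit = np.zeros(len(truth), dtype=bool)
    for i, t in enumerate(truth):
        for c in calls.overlapping(t.chrom, t.start, t.end):
            if t.reciprocal_overlap(c) >= min_fraction:
                hit[i] = True
                break
    return hit
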