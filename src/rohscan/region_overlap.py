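"""Overlap of called ROHs with candidate genomic regions (BED I/O)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rohscan.genotype_io import MarkerMap
from rohscan.roh_detection import ROHSet


class BedFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive chromosome interval."""

    chrom: int
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.chrom <= 29:
            raise ValueError(f"chromosome {self.chrom} outside autosomes 1-29")
        if self.start_bp > self.end_bp:
            raise ValueError("interval start must not exceed end")
        if self.start_bp < 1:
            raise ValueError("positions are 1-based")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def read_bed(source) -> list[GenomicInterval]:
    """Read a 3+ column BED file (0-based half-open) into 1-based intervals."""
    close = False
    if not hasattr(source, "read"):
        source = open(source)
        close = True
    intervals: list[GenomicInterval] = []
    try:
        for lineno, line in enumerate(source, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise BedFormatError(f"BED line {lineno}: fewer than 3 columns")
            chrom_s = parts[0]
            if chrom_s.lower().startswith("chr"):
                chrom_s = chrom_s[3:]
            try:
                chrom = int(chrom_s)
                start0 = int(parts[1])
                end0 = int(parts[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"BED line {lineno}: non-numeric field"
                ) from exc
            if start0 >= end0:
                raise BedFormatError(
                    f"BED line {lineno}: start {start0} >= end {end0}"
                )
            label = parts[3] if len(parts) > 3 else f"region_{lineno}"
            intervals.append(GenomicInterval(chrom, start0 + 1, end0, label))
    finally:
        if close:
            source.close()
    return intervals


def write_bed(intervals: list[GenomicInterval], dest) -> None:
    """Write intervals back to 0-based half-open BED."""
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        for iv in intervals:
            dest.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.label}\n")
    finally:
        if close:
            dest.close()


@dataclass
class OverlapReport:
    """ROH-vs-candidate-region overlap statistics."""

    n_roh_total: int
    n_roh_overlapping: int
    pct_overlapping: float
    n_regions_hit: int
    per_region_froh: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_roh_total\t{self.n_roh_total}\n")
            fh.write(f"n_roh_overlapping\t{self.n_roh_overlapping}\n")
            fh.write(f"pct_overlapping\t{self.pct_overlapping:.2f}\n")
            fh.write(f"n_regions_hit\t{self.n_regions_hit}\n")
            for label, froh in self.per_region_froh.items():
                fh.write(f"region_froh\t{label}\t{froh:.6f}\n")


def overlap(
    roh_set: ROHSet,
    intervals: list[GenomicInterval],
    min_overlap_bp: int = 1,
) -> OverlapReport:
    """Count ROHs sharing at least ``min_overlap_bp`` with any interval.

    Each ROH is counted once however many intervals it touches; the
    percentage is over all segments in ``roh_set`` (the pooled total of
    whatever populations it contains).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    n_total = roh_set.n_segments
    n_overlapping = 0
    regions_hit: set[str] = set()
    for seg in roh_set.segments:
        hit = False
        for iv in intervals:
            if seg.overlap_bp(iv.chrom, iv.start_bp, iv.end_bp) >= min_overlap_bp:
                hit = True
                regions_hit.add(iv.label)
        if hit:
            n_overlapping += 1
    pct = 100.0 * n_overlapping / n_total if n_total else 0.0
    per_region = {
        iv.label: region_froh(roh_set, iv, len(roh_set.samples) or 1)
        for iv in intervals
    }
    return OverlapReport(
        n_roh_total=n_total,
        n_roh_overlapping=n_overlapping,
        pct_overlapping=pct,
        n_regions_hit=len(regions_hit),
        per_region_froh=per_region,
    )


def region_froh(
    roh_set: ROHSet, interval: GenomicInterval, n_samples: int
) -> float:
    """Mean over samples of the fraction of the interval covered by ROHs."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    total = 0
    for seg in roh_set.segments:
        total += seg.overlap_bp(interval.chrom, interval.start_bp, interval.end_bp)
    return total / (n_samples * interval.length_bp)


def snp_incidence(roh_set: ROHSet, marker_map: MarkerMap) -> np.ndarray:
    """Per-marker fraction of samples whose ROHs cover the marker."""
    n_samples = len(roh_set.samples)
    counts = np.zeros(marker_map.n_markers, dtype=np.int64)
    if n_samples == 0:
        return counts.astype(float)
    by_chrom: dict[int, np.ndarray] = {}
    order_by_chrom: dict[int, np.ndarray] = {}
    for chrom in marker_map.chromosomes():
        cidx = marker_map.chrom_indices(chrom)
        order = np.argsort(marker_map.pos_bp[cidx], kind="stable")
        order_by_chrom[chrom] = cidx[order]
        by_chrom[chrom] = marker_map.pos_bp[cidx[order]]
    for seg in roh_set.segments:
        pos = by_chrom.get(seg.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, seg.start_bp, side="left")
        hi = np.searchsorted(pos, seg.end_bp, side="right")
        counts[order_by_chrom[seg.chrom][lo:hi]] += 1
    return counts / n_samples
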