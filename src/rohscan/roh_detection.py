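"""Sliding-window detection of runs of homozygosity.

A window of ``window_snps`` consecutive markers is a *hit* when it contains
at most ``max_het_per_window`` heterozygous and ``max_miss_per_window``
missing calls.  Each SNP receives a support fraction (hit windows spanning
it / windows spanning it); SNPs at or above ``window_threshold`` are
candidates, and maximal candidate stretches — split at genotyping gaps
wider than ``max_gap_bp`` — become ROHs when they satisfy the length, SNP
count and density thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rohscan.genotype_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("4-8", "8-16", ">16")


@dataclass(frozen=True)
class ROHParams:
    """Detection parameters; defaults follow the 50K-chip convention."""

    window_snps: int = 20
    max_miss_per_window: int = 1
    max_het_per_window: int = 1
    min_length_bp: int = 4_000_000
    min_density_snp_per_bp: float = 1.0 / 100_000
    max_gap_bp: int = 1_000_000
    window_threshold: float = 0.05
    min_snps_in_run: int = 20

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_length_bp < 1 or self.max_gap_bp < 1:
            raise ValueError("ROHParams sizes must be positive")
        if self.min_snps_in_run < 1 or self.min_density_snp_per_bp <= 0:
            raise ValueError("ROHParams sizes must be positive")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must lie in (0, 1]")
        if self.max_miss_per_window < 0 or self.max_het_per_window < 0:
            raise ValueError("per-window caps must be non-negative")


@dataclass
class ROHSegment:
    """One called run: 1-based inclusive SNP-boundary coordinates."""

    sample_id: str
    population: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    size_class: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlap_bp(self, chrom: int, start_bp: int, end_bp: int) -> int:
        if self.chrom != chrom:
            return 0
        return max(0, min(self.end_bp, end_bp) - max(self.start_bp, start_bp) + 1)


@dataclass
class ROHSet:
    """Called segments plus the parameters used and the sample roster."""

    segments: list[ROHSegment]
    params: ROHParams
    samples: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            seen: dict[str, str] = {}
            for s in self.segments:
                seen.setdefault(s.sample_id, s.population)
            self.samples = list(seen.items())

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pop in self.samples:
            seen.setdefault(pop, None)
        return list(seen)

    def s_roh(self) -> dict[str, int]:
        """Per-sample total ROH length in bp (zero for ROH-free samples)."""
        totals = {sid: 0 for sid, _ in self.samples}
        for seg in self.segments:
            totals[seg.sample_id] = totals.get(seg.sample_id, 0) + seg.length_bp
        return totals

    def for_sample(self, sample_id: str) -> list[ROHSegment]:
        return [s for s in self.segments if s.sample_id == sample_id]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": s.sample_id,
                    "population": s.population,
                    "chrom": s.chrom,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "n_snps": s.n_snps,
                    "length_bp": s.length_bp,
                    "class": s.size_class if s.size_class is not None else "",
                }
                for s in self.segments
            ],
            columns=[
                "sample",
                "population",
                "chrom",
                "start_bp",
                "end_bp",
                "n_snps",
                "length_bp",
                "class",
            ],
        )

    def to_tsv(self, path: str) -> None:
        """Tab-separated segment table; sample roster kept in '##' headers."""
        with open(path, "w") as fh:
            for sid, pop in self.samples:
                fh.write(f"##sample\t{sid}\t{pop}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    def to_bed(self, path: str) -> None:
        """0-based half-open BED, one line per segment."""
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(
                    f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t"
                    f"{s.sample_id}\n"
                )


def read_roh_tsv(path: str, params: ROHParams | None = None) -> ROHSet:
    """Read a segment table written by :meth:`ROHSet.to_tsv`."""
    samples: list[tuple[str, str]] = []
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sample\t"):
                _, sid, pop = line.rstrip("\n").split("\t")
                samples.append((sid, pop))
            else:
                rows.append(line)
    import io

    df = pd.read_csv(io.StringIO("".join(rows)), sep="\t", dtype={"sample": str})
    segments = [
        ROHSegment(
            sample_id=str(r["sample"]),
            population=str(r["population"]),
            chrom=int(r["chrom"]),
            start_bp=int(r["start_bp"]),
            end_bp=int(r["end_bp"]),
            n_snps=int(r["n_snps"]),
            size_class=str(r["class"]) if not pd.isna(r["class"]) else None,
        )
        for _, r in df.iterrows()
    ]
    return ROHSet(segments, params or ROHParams(), samples)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def scan_windows(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Per-SNP window-support fractions for one sample on one chromosome.

    ``fraction[j]`` = hit windows containing SNP j / windows containing
    SNP j.  Edge SNPs are contained in fewer windows.  Positions must be
    sorted; fewer SNPs than one window yields an empty-to-call all-zero
    result handled by the caller.
    """
    positions = np.asarray(positions)
    if positions.size > 1 and np.any(np.diff(positions) < 0):
        raise RuntimeError("marker positions must be pre-sorted")
    g = np.asarray(genotypes)
    n = g.size
    w = params.window_snps
    if n < w:
        return np.zeros(n)
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(n - w + 1)
    hit = (
        (chet[starts + w] - chet[starts] <= params.max_het_per_window)
        & (cmis[starts + w] - cmis[starts] <= params.max_miss_per_window)
    ).astype(np.int64)
    chit = np.concatenate([[0], np.cumsum(hit)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_windows = hi - lo + 1
    n_hits = chit[hi + 1] - chit[lo]
    return n_hits / n_windows


def _stretch_to_segments(
    cand_idx: np.ndarray,
    positions: np.ndarray,
    params: ROHParams,
    sample_id: str,
    population: str,
    chrom: int,
) -> list[ROHSegment]:
    """Split candidate index stretches at large gaps and apply run filters."""
    if cand_idx.size == 0:
        return []
    segments: list[ROHSegment] = []
    # break consecutive-index runs
    breaks = np.nonzero(np.diff(cand_idx) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [cand_idx.size - 1]])
    for s, e in zip(starts, ends):
        run = cand_idx[s : e + 1]
        # split at genotyping gaps wider than max_gap_bp
        gaps = np.diff(positions[run])
        gap_breaks = np.nonzero(gaps > params.max_gap_bp)[0]
        sub_starts = np.concatenate([[0], gap_breaks + 1])
        sub_ends = np.concatenate([gap_breaks, [run.size - 1]])
        for ss, se in zip(sub_starts, sub_ends):
            sub = run[ss : se + 1]
            start_bp = int(positions[sub[0]])
            end_bp = int(positions[sub[-1]])
            length = end_bp - start_bp + 1
            n_snps = int(sub.size)
            if length < params.min_length_bp:
                continue
            if n_snps < params.min_snps_in_run:
                continue
            if n_snps / length < params.min_density_snp_per_bp:
                continue
            segments.append(
                ROHSegment(sample_id, population, chrom, start_bp, end_bp, n_snps)
            )
    return segments


def call_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Call ROHs for every sample and autosome of ``dataset``."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    skipped: set[int] = set()
    for chrom in sorted(dataset.markers.chromosomes()):
        cidx = dataset.markers.chrom_indices(chrom)
        order = np.argsort(dataset.markers.pos_bp[cidx], kind="stable")
        cidx = cidx[order]
        positions = dataset.markers.pos_bp[cidx]
        if cidx.size < params.window_snps:
            if chrom not in skipped:
                logger.warning(
                    "chromosome %d has %d SNPs (< window of %d): skipped",
                    chrom,
                    cidx.size,
                    params.window_snps,
                )
                skipped.add(chrom)
            continue
        for i in range(dataset.n_samples):
            row = dataset.genotypes[i, cidx]
            frac = scan_windows(row, positions, params)
            cand = np.nonzero(frac >= params.window_threshold)[0]
            segments.extend(
                _stretch_to_segments(
                    cand,
                    positions,
                    params,
                    dataset.sample_id[i],
                    dataset.population[i],
                    chrom,
                )
            )
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    roster = list(zip(dataset.sample_id, dataset.population))
    return classify_roh(ROHSet(segments, params, roster))


def classify_roh(
    roh_set: ROHSet, breaks_mb: tuple[float, float, float] = (4.0, 8.0, 16.0)
) -> ROHSet:
    """Label segments with left-closed size classes (4-8, 8-16, >16 Mb)."""
    b0, b1, b2 = (b * 1_000_000 for b in breaks_mb)
    labels = (
        f"{breaks_mb[0]:g}-{breaks_mb[1]:g}",
        f"{breaks_mb[1]:g}-{breaks_mb[2]:g}",
        f">{breaks_mb[2]:g}",
    )
    segments = []
    for s in roh_set.segments:
        L = s.length_bp
        if L < b0:
            raise RuntimeError(
                f"segment of {L} bp is below the first class break; "
                "inconsistent with the calling length filter"
            )
        if L < b1:
            cls = labels[0]
        elif L < b2:
            cls = labels[1]
        else:
            cls = labels[2]
        segments.append(replace(s, size_class=cls))
    return ROHSet(segments, roh_set.params, list(roh_set.samples))
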