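"""Genomic inbreeding (F_ROH) statistics and per-class summaries.

F_ROH is the summed ROH length of an individual divided by the autosomal
genome length covered by markers.  Cumulative variants restrict the sum to
segments at or above a minimum length, and per-chromosome variants divide
by the covered span of each chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rohscan.genotype_io import MarkerMap
from rohscan.roh_detection import ROHSet

logger = logging.getLogger(__name__)

#: Autosomal genome length covered by the 50K chip, in bp.
DEFAULT_L_AUTOSOME = 2_504_168_970


@dataclass
class GenomeConstants:
    """Denominators for F_ROH: total and per-chromosome covered lengths."""

    l_autosome: int = DEFAULT_L_AUTOSOME
    l_bta: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.l_autosome <= 0:
            raise ValueError("l_autosome must be positive")
        total = sum(self.l_bta.values())
        if total > self.l_autosome * 1.05:
            raise ValueError(
                f"per-chromosome spans sum to {total} bp, exceeding "
                f"l_autosome = {self.l_autosome}"
            )


def covered_chromosome_lengths(marker_map: MarkerMap) -> dict[int, int]:
    """Covered span (max - min position + 1) per chromosome.

    Chromosomes with fewer than two markers have no defined span and are
    excluded with a warning.
    """
    lengths: dict[int, int] = {}
    for chrom in sorted(marker_map.chromosomes()):
        pos = marker_map.pos_bp[marker_map.chrom_indices(chrom)]
        if pos.size < 2:
            logger.warning(
                "chromosome %d has %d marker(s); covered length undefined",
                chrom,
                pos.size,
            )
            continue
        lengths[chrom] = int(pos.max() - pos.min() + 1)
    return lengths


@dataclass
class FrohRecord:
    """Per-individual genomic inbreeding values."""

    sample_id: str
    population: str
    n_roh: int
    s_roh_bp: int
    froh_total: float
    froh_ge_4: float
    froh_ge_8: float
    froh_gt_16: float
    froh_by_chrom: dict[int, float]


def froh_individual(
    roh_set: ROHSet,
    constants: GenomeConstants,
    thresholds_mb: tuple[float, float, float] = (4.0, 8.0, 16.0),
) -> list[FrohRecord]:
    """One :class:`FrohRecord` per rostered sample (zeros when ROH-free)."""
    t4, t8, t16 = (t * 1_000_000 for t in thresholds_mb)
    per_chrom_all = froh_per_chromosome(roh_set, constants)
    records = []
    for sample_id, population in roh_set.samples:
        segs = roh_set.for_sample(sample_id)
        s_roh = sum(s.length_bp for s in segs)
        L = constants.l_autosome
        records.append(
            FrohRecord(
                sample_id=sample_id,
                population=population,
                n_roh=len(segs),
                s_roh_bp=s_roh,
                froh_total=s_roh / L,
                froh_ge_4=sum(s.length_bp for s in segs if s.length_bp >= t4) / L,
                froh_ge_8=sum(s.length_bp for s in segs if s.length_bp >= t8) / L,
                froh_gt_16=sum(s.length_bp for s in segs if s.length_bp >= t16) / L,
                froh_by_chrom=per_chrom_all[sample_id],
            )
        )
    return records


def froh_per_chromosome(
    roh_set: ROHSet, constants: GenomeConstants
) -> dict[str, dict[int, float]]:
    """Per-sample, per-chromosome ROH fraction of the covered span."""
    chroms = sorted(constants.l_bta)
    result = {
        sid: {c: 0.0 for c in chroms} for sid, _ in roh_set.samples
    }
    sums: dict[tuple[str, int], int] = {}
    for seg in roh_set.segments:
        if seg.chrom not in constants.l_bta:
            raise ValueError(
                f"segment on chromosome {seg.chrom} but no covered length "
                "is defined for it"
            )
        key = (seg.sample_id, seg.chrom)
        sums[key] = sums.get(key, 0) + seg.length_bp
    for (sid, chrom), total in sums.items():
        result[sid][chrom] = total / constants.l_bta[chrom]
    return result


@dataclass
class ClassSummary:
    """Descriptive statistics of segment lengths for one population/class."""

    population: str
    size_class: str
    n_roh: int
    freq_pct: float | None = None
    mn_roh_mb: float | None = None
    sd_mb: float | None = None
    cv_pct: float | None = None
    ci95_low: float | None = None
    ci95_high: float | None = None


def cv_pct(mean: float, sd: float) -> float:
    """Coefficient of variation as a percentage, 100 * sd / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def class_summary(roh_set: ROHSet) -> list[ClassSummary]:
    """Counts, class frequencies and length statistics per population/class.

    95% confidence bounds use the normal approximation
    mean +/- 1.96 * sd / sqrt(n).  Classes with a single segment have no
    dispersion statistics; empty classes report only n = 0.
    """
    classes: dict[str, None] = {}
    for s in roh_set.segments:
        if s.size_class is None:
            raise ValueError("class_summary requires a classified ROHSet")
        classes.setdefault(s.size_class, None)
    class_order = list(classes)
    out: list[ClassSummary] = []
    for population in roh_set.populations():
        pop_segs = [s for s in roh_set.segments if s.population == population]
        n_total = len(pop_segs)
        for cls in class_order:
            lengths_mb = np.array(
                [s.length_bp / 1e6 for s in pop_segs if s.size_class == cls]
            )
            n = lengths_mb.size
            if n == 0:
                out.append(ClassSummary(population, cls, 0))
                continue
            freq = 100.0 * n / n_total
            mean = float(lengths_mb.mean())
            if n == 1:
                out.append(
                    ClassSummary(population, cls, n, freq_pct=freq, mn_roh_mb=mean)
                )
                continue
            sd = float(lengths_mb.std(ddof=1))
            half = 1.96 * sd / math.sqrt(n)
            out.append(
                ClassSummary(
                    population,
                    cls,
                    n,
                    freq_pct=freq,
                    mn_roh_mb=mean,
                    sd_mb=sd,
                    cv_pct=cv_pct(mean, sd),
                    ci95_low=mean - half,
                    ci95_high=mean + half,
                )
            )
    return out


def population_mean_froh(records: list[FrohRecord]) -> pd.DataFrame:
    """Mean and SD of the cumulative F_ROH columns per population."""
    df = pd.DataFrame(
        [
            {
                "population": r.population,
                "froh_ge_4": r.froh_ge_4,
                "froh_ge_8": r.froh_ge_8,
                "froh_gt_16": r.froh_gt_16,
            }
            for r in records
        ]
    )
    agg = df.groupby("population", sort=False).agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    return agg.reset_index()


def froh_report(
    records: list[FrohRecord],
    summaries: list[ClassSummary],
    out_dir: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Deterministic tabular outputs (and plot-ready data frames).

    Returns per-sample F_ROH, class summaries, per-chromosome boxplot data
    (quartiles/extremes per population x chromosome) and per-sample
    (n_roh, S_ROH) scatter data; writes them as TSV files when ``out_dir``
    is given.
    """
    per_sample = pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "population": r.population,
                "n_roh": r.n_roh,
                "s_roh_bp": r.s_roh_bp,
                "froh_total": round(r.froh_total, 6),
                "froh_ge_4": round(r.froh_ge_4, 6),
                "froh_ge_8": round(r.froh_ge_8, 6),
                "froh_gt_16": round(r.froh_gt_16, 6),
            }
            for r in records
        ],
        columns=[
            "sample",
            "population",
            "n_roh",
            "s_roh_bp",
            "froh_total",
            "froh_ge_4",
            "froh_ge_8",
            "froh_gt_16",
        ],
    )

    summary_df = pd.DataFrame(
        [
            {
                "population": s.population,
                "class": s.size_class,
                "n_roh": s.n_roh,
                "freq_pct": None if s.freq_pct is None else round(s.freq_pct, 1),
                "mn_roh_mb": None if s.mn_roh_mb is None else round(s.mn_roh_mb, 3),
                "sd_mb": None if s.sd_mb is None else round(s.sd_mb, 3),
                "cv_pct": None if s.cv_pct is None else round(s.cv_pct, 1),
                "ci95_low": None if s.ci95_low is None else round(s.ci95_low, 3),
                "ci95_high": None if s.ci95_high is None else round(s.ci95_high, 3),
            }
            for s in summaries
        ],
        columns=[
            "population",
            "class",
            "n_roh",
            "freq_pct",
            "mn_roh_mb",
            "sd_mb",
            "cv_pct",
            "ci95_low",
            "ci95_high",
        ],
    )

    box_rows = []
    by_pop: dict[str, list[FrohRecord]] = {}
    for r in records:
        by_pop.setdefault(r.population, []).append(r)
    for population, recs in by_pop.items():
        chroms = sorted({c for r in recs for c in r.froh_by_chrom})
        for chrom in chroms:
            vals = np.array([r.froh_by_chrom.get(chrom, 0.0) for r in recs])
            box_rows.append(
                {
                    "population": population,
                    "chrom": chrom,
                    "min": round(float(vals.min()), 6),
                    "q1": round(float(np.percentile(vals, 25)), 6),
                    "median": round(float(np.percentile(vals, 50)), 6),
                    "q3": round(float(np.percentile(vals, 75)), 6),
                    "max": round(float(vals.max()), 6),
                }
            )
    boxplot = pd.DataFrame(
        box_rows,
        columns=["population", "chrom", "min", "q1", "median", "q3", "max"],
    )

    scatter = pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "population": r.population,
                "n_roh": r.n_roh,
                "s_roh_mb": round(r.s_roh_bp / 1e6, 3),
            }
            for r in records
        ],
        columns=["sample", "population", "n_roh", "s_roh_mb"],
    )

    tables = {
        "froh_per_sample": per_sample,
        "class_summary": summary_df,
        "froh_by_chrom_boxplot": boxplot,
        "nroh_sroh_scatter": scatter,
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    return tables


def plot_report(tables: dict[str, pd.DataFrame], out_dir: str) -> list[str]:
    """Optional PNG rendering of the boxplot/scatter tables."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    box = tables["froh_by_chrom_boxplot"]
    if not box.empty:
        fig, ax = plt.subplots(figsize=(10, 4))
        for population, grp in box.groupby("population"):
            ax.plot(grp["chrom"], grp["median"], marker="o", label=population)
            ax.fill_between(grp["chrom"], grp["q1"], grp["q3"], alpha=0.2)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("F_ROH per chromosome")
        ax.legend()
        path = os.path.join(out_dir, "froh_by_chrom.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    scatter = tables["nroh_sroh_scatter"]
    if not scatter.empty:
        fig, ax = plt.subplots(figsize=(5, 5))
        for population, grp in scatter.groupby("population"):
            ax.scatter(grp["s_roh_mb"], grp["n_roh"], label=population, s=12)
        ax.set_xlabel("total ROH length (Mb)")
        ax.set_ylabel("number of ROHs")
        ax.legend()
        path = os.path.join(out_dir, "nroh_vs_sroh.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
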