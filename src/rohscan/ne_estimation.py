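"""LD-based effective-population-size trajectory estimation.

Intra-chromosomal marker pairs are binned by physical distance; the mean
sample-size-adjusted composite r^2 in a bin at recombination fraction c
maps to the effective size N_T = (1/E[r2_adj] - alpha) / (4 f(c)) at
t = 1/(2 f(c)) generations in the past.  f(c) is the identity; the
physical-to-genetic mapping (linear by default) is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rohscan.genotype_io import GenotypeDataset, _maf, _pairwise_r2

logger = logging.getLogger(__name__)

MAPPINGS = ("linear", "haldane", "sved_feldman")


@dataclass(frozen=True)
class NeConfig:
    """Parameters of the LD -> Ne pipeline."""

    maf_min: float = 0.05
    mindist_bp: int = 2_400_000
    maxdist_bp: int = 50_000_000
    alpha: float = 2.2
    recomb_rate_per_bp: float = 1e-8
    mapping: str = "linear"
    phase_known: bool = False
    generations: tuple[int, ...] = tuple(range(1, 36))
    min_pairs_per_bin: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.mindist_bp < self.maxdist_bp:
            raise ValueError("need 0 < mindist_bp < maxdist_bp")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.recomb_rate_per_bp <= 0:
            raise ValueError("recombination rate must be positive")
        if self.mapping not in MAPPINGS:
            raise ValueError(f"mapping must be one of {MAPPINGS}")


@dataclass
class LDBin:
    """One distance bin with its adjusted LD and mapped (t, N_T) values."""

    d_low: int
    d_high: int
    n_pairs: int
    mean_r2: float
    mean_r2_adj: float
    c: float
    t: float
    ne: float
    valid: bool = True


@dataclass
class NeTrajectory:
    """Ordered (t, N_T) series for one population."""

    bins: list[LDBin]
    config: NeConfig
    population: str = ""

    def __post_init__(self) -> None:
        ts = [b.t for b in self.bins]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("bin t values must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "population": self.population,
                    "t": round(b.t, 3),
                    "d_low": b.d_low,
                    "d_high": b.d_high,
                    "n_pairs": b.n_pairs,
                    "mean_r2": round(b.mean_r2, 6),
                    "mean_r2_adj": round(b.mean_r2_adj, 6),
                    "c": round(b.c, 6),
                    "ne": round(b.ne, 2) if b.valid else float("nan"),
                }
                for b in self.bins
            ],
            columns=[
                "population",
                "t",
                "d_low",
                "d_high",
                "n_pairs",
                "mean_r2",
                "mean_r2_adj",
                "c",
                "ne",
            ],
        )

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def r2_composite(genotype_col_1: np.ndarray, genotype_col_2: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 dosages, pairwise-complete.

    Returns NaN when fewer than two complete observations remain or either
    column is monomorphic among them (composite LD for unphased data).
    """
    x = np.asarray(genotype_col_1, dtype=float)
    y = np.asarray(genotype_col_2, dtype=float)
    x = np.where(x == -1, np.nan, x)
    y = np.where(y == -1, np.nan, y)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def collect_pairs(
    dataset: GenotypeDataset, config: NeConfig
) -> tuple[np.ndarray, np.ndarray]:
    """All intra-chromosomal (distance_bp, r^2) pairs inside the window.

    Markers below ``config.maf_min`` are excluded first; pairs with an
    undefined r^2 are dropped.
    """
    maf = _maf(dataset.genotypes)
    eligible = maf >= config.maf_min
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for chrom in sorted(dataset.markers.chromosomes()):
        cidx = dataset.markers.chrom_indices(chrom)
        cidx = cidx[eligible[cidx]]
        if cidx.size < 2:
            continue
        order = np.argsort(dataset.markers.pos_bp[cidx], kind="stable")
        cidx = cidx[order]
        pos = dataset.markers.pos_bp[cidx].astype(np.int64)
        d = pos[None, :] - pos[:, None]
        iu = np.triu_indices(cidx.size, k=1)
        dvals = d[iu]
        inwin = (dvals >= config.mindist_bp) & (dvals <= config.maxdist_bp)
        if not inwin.any():
            continue
        r2 = _pairwise_r2(dataset.genotypes[:, cidx])[iu]
        dvals, r2 = dvals[inwin], r2[inwin]
        keep = ~np.isnan(r2)
        dists.append(dvals[keep])
        r2s.append(r2[keep])
    if not dists:
        logger.warning("no eligible marker pairs in the distance window")
        return np.array([], dtype=np.int64), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def adjust_sample_size(r2: float, n: int, phase_known: bool = False) -> float:
    """Subtract the finite-sample expectation 1/(beta*n), floored at zero.

    With known gametic phase there are 2n observed gametes (beta = 2); for
    unphased genotype-based composite r^2 the chance correlation of n dosage
    vectors is ~1/n (beta = 1).
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    beta = 2.0 if phase_known else 1.0
    return max(r2 - 1.0 / (beta * n), 0.0)


def bp_to_c(d_bp: float, config: NeConfig) -> float:
    """Physical distance to recombination fraction, capped at 0.5."""
    h = d_bp * config.recomb_rate_per_bp
    if config.mapping == "linear":
        c = h
    elif config.mapping == "haldane":
        c = 0.5 * (1.0 - math.exp(-2.0 * h))
    else:  # sved_feldman
        c = h / (1.0 + 2.0 * h)
    return min(c, 0.5)


def ne_from_bin(mean_r2_adj: float, c: float, alpha: float) -> tuple[float, bool]:
    """Effective size from a bin's mean adjusted r^2 at recombination c.

    Returns ``(ne, valid)``; a non-positive r^2 or a negative size (when
    1/r^2 < alpha) flags the bin invalid.
    """
    if mean_r2_adj <= 0:
        return float("nan"), False
    ne = (1.0 / mean_r2_adj - alpha) / (4.0 * c)
    if ne < 0:
        return ne, False
    return ne, True


def expected_r2_constant(
    N: float,
    c: float,
    n: int | None = None,
    alpha: float = 1.0,
    phase_known: bool = False,
) -> float:
    """Drift-equilibrium expectation 1/(alpha + 4Nc) plus the sample term."""
    if N <= 0 or c <= 0 or alpha <= 0:
        raise ValueError("N, c and alpha must be positive")
    r2 = 1.0 / (alpha + 4.0 * N * c)
    if n is not None:
        beta = 2.0 if phase_known else 1.0
        r2 += 1.0 / (beta * n)
    return r2


# ---------------------------------------------------------------------------
# trajectory estimation
# ---------------------------------------------------------------------------


def _generation_bin_edges(t: int, config: NeConfig) -> tuple[int, int] | None:
    """Distance bounds (bp) for the bin targeting generation ``t``.

    The bin spans t +/- 0.5 generations via d = 1/(2 t rate), intersected
    with the configured distance window.
    """
    rate = config.recomb_rate_per_bp
    d_low = 1.0 / (2.0 * (t + 0.5) * rate)
    d_high = 1.0 / (2.0 * (t - 0.5) * rate) if t > 0.5 else float("inf")
    d_low = max(d_low, config.mindist_bp)
    d_high = min(d_high, config.maxdist_bp)
    if d_low >= d_high:
        return None
    return int(round(d_low)), int(round(d_high))


def estimate_ne(dataset: GenotypeDataset, config: NeConfig | None = None) -> NeTrajectory:
    """Estimate the (t, N_T) trajectory for one population sample."""
    config = config or NeConfig()
    if dataset.n_samples < 2:
        raise ValueError("Ne estimation needs at least two samples")
    dists, r2s = collect_pairs(dataset, config)
    n = dataset.n_samples
    bins: list[LDBin] = []
    for t in sorted(config.generations):
        edges = _generation_bin_edges(t, config)
        if edges is None:
            continue
        d_low, d_high = edges
        sel = (dists >= d_low) & (dists < d_high)
        n_pairs = int(sel.sum())
        if n_pairs < config.min_pairs_per_bin:
            continue
        mean_r2 = float(r2s[sel].mean())
        adj = np.maximum(
            r2s[sel] - 1.0 / ((2.0 if config.phase_known else 1.0) * n), 0.0
        )
        mean_adj = float(adj.mean())
        c = bp_to_c((d_low + d_high) / 2.0, config)
        t_out = 1.0 / (2.0 * c)
        ne, valid = ne_from_bin(mean_adj, c, config.alpha)
        bins.append(LDBin(d_low, d_high, n_pairs, mean_r2, mean_adj, c, t_out, ne, valid))
    if not bins:
        raise ValueError("no distance bin had enough eligible pairs")
    bins.sort(key=lambda b: b.t)
    populations = sorted(set(dataset.population))
    label = populations[0] if len(populations) == 1 else "+".join(populations)
    return NeTrajectory(bins, config, label)
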