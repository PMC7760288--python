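"""Synthetic genotype generators with known truth.

Two generators back the test battery: a direct ROH-implant generator
(background genotypes with forced homozygous tracts at known coordinates)
and a forward Wright-Fisher simulator with an arbitrary N(t) trajectory
that records the full pedigree, so true pedigree inbreeding accompanies
the genotypes.  Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rohscan.genotype_io import GenotypeDataset, MarkerMap
from rohscan.region_overlap import GenomicInterval
from rohscan.roh_detection import ROHSegment


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# implant generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImplantConfig:
    """Background-plus-implants dataset description.

    ``implants`` holds (sample_index, chrom, start_bp, length_bp) tuples.
    Background genotypes are heterozygous with probability ``het_prob``,
    the remainder split evenly between the two homozygotes.
    """

    n_samples: int
    seed: int
    n_chrom: int = 1
    snps_per_chrom: int = 100
    mean_spacing_bp: int = 85_000
    het_prob: float = 0.5
    implants: tuple[tuple[int, int, int, int], ...] = ()
    population: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_chrom < 1 or self.snps_per_chrom < 1:
            raise ConfigError("counts must be positive")
        if not 1 <= self.n_chrom <= 29:
            raise ConfigError("n_chrom must be within the 29 autosomes")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ConfigError("het_prob must lie in [0, 1]")
        if self.mean_spacing_bp < 2:
            raise ConfigError("mean_spacing_bp too small")


def implant_roh_dataset(
    config: ImplantConfig,
) -> tuple[GenotypeDataset, list[ROHSegment]]:
    """Generate the dataset and the exact SNP-boundary truth segments."""
    rng = np.random.default_rng(config.seed)
    ids: list[str] = []
    chroms: list[int] = []
    pos: list[int] = []
    span: dict[int, tuple[int, int]] = {}
    for ch in range(1, config.n_chrom + 1):
        lo = max(2, int(config.mean_spacing_bp * 0.5))
        hi = int(config.mean_spacing_bp * 1.5) + 1
        spacings = rng.integers(lo, hi, size=config.snps_per_chrom)
        p = np.cumsum(spacings)
        pos.extend(int(x) for x in p)
        chroms.extend([ch] * config.snps_per_chrom)
        ids.extend(f"c{ch}_m{j}" for j in range(config.snps_per_chrom))
        span[ch] = (int(p[0]), int(p[-1]))

    markers = MarkerMap(
        np.array(ids, dtype=object),
        chroms,
        pos,
        np.array(["A"] * len(ids), dtype=object),
        np.array(["B"] * len(ids), dtype=object),
    )
    n_markers = markers.n_markers
    u = rng.random((config.n_samples, n_markers))
    p = config.het_prob
    genotypes = np.where(u < p, 1, np.where(u < p + (1.0 - p) / 2.0, 0, 2)).astype(
        np.int8
    )

    seen: dict[tuple[int, int], list[tuple[int, int]]] = {}
    truth: list[ROHSegment] = []
    pos_arr = markers.pos_bp
    for sample, ch, start_bp, length_bp in config.implants:
        if not 0 <= sample < config.n_samples:
            raise ConfigError(f"implant sample index {sample} out of range")
        if ch not in span:
            raise ConfigError(f"implant chromosome {ch} not in dataset")
        end_bp = start_bp + length_bp - 1
        if start_bp < 1 or end_bp > span[ch][1]:
            raise ConfigError(
                f"implant ({sample}, {ch}, {start_bp}, {length_bp}) exceeds "
                f"the chromosome span {span[ch]}"
            )
        for s0, e0 in seen.setdefault((sample, ch), []):
            if start_bp <= e0 and end_bp >= s0:
                raise ConfigError(
                    f"overlapping implants on sample {sample} chromosome {ch}"
                )
        seen[(sample, ch)].append((start_bp, end_bp))
        in_span = (markers.chrom == ch) & (pos_arr >= start_bp) & (pos_arr <= end_bp)
        idx = np.nonzero(in_span)[0]
        genotypes[sample, idx] = 0
        if idx.size:
            truth.append(
                ROHSegment(
                    sample_id=f"S{sample}",
                    population=config.population,
                    chrom=ch,
                    start_bp=int(pos_arr[idx[0]]),
                    end_bp=int(pos_arr[idx[-1]]),
                    n_snps=int(idx.size),
                )
            )

    sample_ids = [f"S{i}" for i in range(config.n_samples)]
    populations = [config.population] * config.n_samples
    ds = GenotypeDataset(sample_ids, populations, markers, genotypes)
    truth.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return ds, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WFConfig:
    """Forward-simulation description.

    ``ne_trajectory`` is a list of (generations_ago, N) breakpoints; the
    per-generation sizes are linearly interpolated between breakpoints and
    held at the oldest value before the earliest one.  One crossover per
    Morgan (Poisson, no interference); selfing allowed; founder haplotypes
    all distinct.
    """

    ne_trajectory: tuple[tuple[int, int], ...]
    seed: int
    n_chrom: int = 10
    chrom_length_morgans: float = 1.0
    snps_per_chrom: int = 300
    n_sampled_diploids: int = 40
    maf_min: float = 0.05
    recomb_rate_per_bp: float = 1e-8
    population: str = "WF"
    site_oversample: float = 3.0
    #: separate RNG stream for marker positions; two simulations sharing a
    #: site_seed (and panel shape) are genotyped on the same marker panel,
    #: like cohorts run on one chip
    site_seed: int | None = None

    def __post_init__(self) -> None:
        if not self.ne_trajectory:
            raise ConfigError("ne_trajectory must have at least one breakpoint")
        if any(N < 2 for _, N in self.ne_trajectory):
            raise ConfigError("population size must be >= 2 in every generation")
        if any(t < 0 for t, _ in self.ne_trajectory):
            raise ConfigError("generations_ago must be non-negative")
        if self.chrom_length_morgans <= 0:
            raise ConfigError("chromosome length must be positive")
        if not 1 <= self.n_chrom <= 29:
            raise ConfigError("n_chrom must be within the 29 autosomes")

    def generation_sizes(self) -> np.ndarray:
        """N per generation, oldest first (index 0 = t_max generations ago)."""
        bp = sorted(self.ne_trajectory, key=lambda x: -x[0])
        t_max = bp[0][0]
        ts = np.array([t for t, _ in bp], dtype=float)
        ns = np.array([N for _, N in bp], dtype=float)
        t_axis = np.arange(t_max, -1, -1, dtype=float)
        sizes = np.interp(-t_axis, -ts, ns)
        return np.maximum(np.round(sizes).astype(int), 2)


@dataclass
class WFTruth:
    """Ground truth accompanying a simulated dataset."""

    generation_sizes: np.ndarray  # oldest first
    f_pedigree: np.ndarray  # per sampled individual
    sampled_ids: list[str] = field(default_factory=list)


def _gamete(hap_pair, L: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Recombine a parent's two haplotypes into one gamete.

    A haplotype is (segment_end_positions, founder_ids) with the last end
    equal to L; haplotypes are treated as immutable and may be shared.
    """
    k = rng.poisson(L)
    first = int(rng.integers(2))
    if k == 0:
        return hap_pair[first]
    cuts = np.sort(rng.random(k)) * L
    ends_out = []
    ids_out = []
    bounds = np.concatenate([cuts, [L]])
    cur = 0.0
    src = first
    for b in bounds:
        if b > cur:
            ends, idv = hap_pair[src]
            i0 = int(np.searchsorted(ends, cur, side="right"))
            i1 = int(np.searchsorted(ends, b, side="left"))
            seg_ends = ends[i0 : i1 + 1].copy()
            seg_ends[-1] = b
            ends_out.append(seg_ends)
            ids_out.append(idv[i0 : i1 + 1])
        src ^= 1
        cur = b
    ends = np.concatenate(ends_out)
    idv = np.concatenate(ids_out)
    if idv.size > 1:
        keep = np.concatenate([idv[:-1] != idv[1:], [True]])
        ends, idv = ends[keep], idv[keep]
    return ends, idv


def simulate_wf(config: WFConfig) -> tuple[GenotypeDataset, WFTruth]:
    """Run the forward simulation and genotype a sample of the last generation."""
    rng = np.random.default_rng(config.seed)
    sizes = config.generation_sizes()
    if config.n_sampled_diploids > sizes[-1]:
        raise ConfigError(
            f"cannot sample {config.n_sampled_diploids} diploids from a final "
            f"generation of {sizes[-1]}"
        )
    L = config.chrom_length_morgans
    n_chrom = config.n_chrom

    n0 = sizes[0]
    pop = []
    hap_id = 0
    for _ in range(n0):
        ind = []
        for _ in range(n_chrom):
            h1 = (np.array([L]), np.array([hap_id], dtype=np.int32))
            h2 = (np.array([L]), np.array([hap_id + 1], dtype=np.int32))
            ind.append((h1, h2))
        hap_id += 2
        pop.append(ind)

    kin = 0.5 * np.eye(n0)
    f_current = np.zeros(n0)
    for g in range(1, sizes.size):
        n_prev, n_g = sizes[g - 1], sizes[g]
        parents = rng.integers(0, n_prev, size=(n_g, 2))
        newpop = []
        for i in range(n_g):
            p, q = parents[i]
            ind = []
            for ch in range(n_chrom):
                ind.append(
                    (
                        _gamete(pop[p][ch], L, rng),
                        _gamete(pop[q][ch], L, rng),
                    )
                )
            newpop.append(ind)
        f_current = kin[parents[:, 0], parents[:, 1]]
        amat = np.zeros((n_g, n_prev))
        rows = np.arange(n_g)
        np.add.at(amat, (rows, parents[:, 0]), 0.5)
        np.add.at(amat, (rows, parents[:, 1]), 0.5)
        kin = amat @ kin @ amat.T
        kin[rows, rows] = 0.5 * (1.0 + f_current)
        pop = newpop

    sample_idx = rng.choice(sizes[-1], size=config.n_sampled_diploids, replace=False)
    sample_idx = np.sort(sample_idx)
    f_ped = f_current[sample_idx]

    ids: list[str] = []
    chroms: list[int] = []
    positions: list[int] = []
    geno_cols: list[np.ndarray] = []
    n = config.n_sampled_diploids
    site_rng = (
        rng if config.site_seed is None else np.random.default_rng(config.site_seed)
    )
    for ch in range(n_chrom):
        n_cand = max(int(config.snps_per_chrom * config.site_oversample), 1)
        pos_m = np.sort(site_rng.random(n_cand)) * L
        # each founder haplotype carries a Bernoulli(1/2) allele per site, so
        # founder LD is ~0 and all sampled LD is generated by drift
        founder_allele = rng.integers(0, 2, size=(2 * n0, n_cand)).astype(np.int8)
        # founder id carried by each sampled haplotype at each site
        hap_ids = np.empty((n, 2, n_cand), dtype=np.int32)
        for si, idx in enumerate(sample_idx):
            for hj, hap in enumerate(pop[idx][ch]):
                ends, idv = hap
                hap_ids[si, hj] = idv[np.searchsorted(ends, pos_m, side="left")]
        site_col = np.arange(n_cand)
        alleles = founder_allele[hap_ids, site_col]  # (n, 2, n_cand)
        dosage = alleles.sum(axis=1).astype(np.int8)
        freq = dosage.sum(axis=0) / (2.0 * n)
        maf = np.minimum(freq, 1.0 - freq)
        keep = np.nonzero(maf >= config.maf_min)[0]
        if keep.size > config.snps_per_chrom:
            sel = np.unique(
                np.round(
                    np.linspace(0, keep.size - 1, config.snps_per_chrom)
                ).astype(int)
            )
            keep = keep[sel]
        if keep.size == 0:
            continue
        pos_bp = np.round(pos_m[keep] / config.recomb_rate_per_bp).astype(np.int64)
        pos_bp = np.maximum(pos_bp, 1)
        # enforce strictly increasing bp after rounding
        uniq = np.concatenate([[True], np.diff(pos_bp) > 0])
        keep = keep[uniq]
        pos_bp = pos_bp[uniq]
        ids.extend(f"c{ch + 1}_s{int(j)}" for j in keep)
        chroms.extend([ch + 1] * keep.size)
        positions.extend(int(x) for x in pos_bp)
        geno_cols.append(dosage[:, keep])

    markers = MarkerMap(
        np.array(ids, dtype=object),
        chroms,
        positions,
        np.array(["A"] * len(ids), dtype=object),
        np.array(["B"] * len(ids), dtype=object),
    )
    genotypes = (
        np.hstack(geno_cols) if geno_cols else np.empty((n, 0), dtype=np.int8)
    )
    sample_ids = [f"{config.population}_{i}" for i in range(n)]
    ds = GenotypeDataset(
        sample_ids, [config.population] * n, markers, genotypes
    )
    truth = WFTruth(
        generation_sizes=sizes, f_pedigree=f_ped, sampled_ids=sample_ids
    )
    return ds, truth


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------


def make_candidate_regions(
    marker_map: MarkerMap,
    n_regions: int,
    seed: int,
    genome_fraction: float = 0.1,
) -> list[GenomicInterval]:
    """Random non-overlapping intervals spanning ~``genome_fraction`` of
    the mapped genome; deterministic by seed."""
    if n_regions < 0:
        raise ConfigError("n_regions must be non-negative")
    if not 0.0 < genome_fraction <= 0.9:
        if n_regions == 0:
            return []
        raise ConfigError("genome_fraction must lie in (0, 0.9]")
    if n_regions == 0:
        return []
    rng = np.random.default_rng(seed)
    spans: dict[int, tuple[int, int]] = {}
    for chrom in marker_map.chromosomes():
        p = marker_map.pos_bp[marker_map.chrom_indices(chrom)]
        if p.size >= 2:
            spans[chrom] = (int(p.min()), int(p.max()))
    if not spans:
        raise ConfigError("marker map has no chromosome with >= 2 markers")
    chrom_list = sorted(spans)
    lengths = np.array([spans[c][1] - spans[c][0] + 1 for c in chrom_list], float)
    total = lengths.sum()
    region_len = int(genome_fraction * total / n_regions)
    if region_len < 1 or region_len > lengths.max():
        raise ConfigError("requested regions exceed the genome span")
    weights = lengths / total
    chosen: dict[int, list[tuple[int, int]]] = {c: [] for c in chrom_list}
    intervals: list[GenomicInterval] = []
    attempts = 0
    while len(intervals) < n_regions:
        attempts += 1
        if attempts > 1000 * n_regions:
            raise ConfigError(
                "could not place non-overlapping regions; requested span is "
                "too large for the genome"
            )
        ci = rng.choice(len(chrom_list), p=weights)
        chrom = chrom_list[ci]
        lo, hi = spans[chrom]
        if hi - lo + 1 < region_len:
            continue
        start = int(rng.integers(lo, hi - region_len + 2))
        end = start + region_len - 1
        if any(start <= e and end >= s for s, e in chosen[chrom]):
            continue
        chosen[chrom].append((start, end))
        intervals.append(
            GenomicInterval(chrom, start, end, f"region_{len(intervals) + 1}")
        )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start_bp))
    return [
        GenomicInterval(iv.chrom, iv.start_bp, iv.end_bp, f"region_{i + 1}")
        for i, iv in enumerate(intervals)
    ]
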