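"""PLINK-format genotype I/O, dataset merging and marker quality control.

Genotypes are held as a samples x markers ``int8`` matrix with codes
``0`` (homozygous for allele A), ``1`` (heterozygous), ``2`` (homozygous
for allele B) and ``MISSING`` (= -1).  Only bovine autosomes (chromosomes
1-29) are retained; anything else is dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING: int = -1

AUTOSOMES = frozenset(range(1, 30))


class PlinkFormatError(ValueError):
    """Raised when a PED/MAP/BED file violates the expected layout."""


class MergeError(ValueError):
    """Raised when datasets cannot be merged (incompatible alleles)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-marker metadata: identifier, chromosome, position and alleles.

    Positions are 1-based base pairs.  ``allele_a`` maps to genotype code 0,
    ``allele_b`` to code 2; a ``'0'`` in ``allele_b`` marks a marker for
    which only one allele was ever observed.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        n = len(self.marker_id)
        for name in ("chrom", "pos_bp", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker_ids are not unique")
        if n and (self.chrom.min() < 1 or self.pos_bp.min() < 1):
            raise ValueError("chromosome and position must be >= 1")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[index],
            self.chrom[index],
            self.pos_bp[index],
            self.allele_a[index],
            self.allele_b[index],
        )

    def chrom_indices(self, chrom: int) -> np.ndarray:
        """Marker indices on ``chrom``, in map order."""
        return np.nonzero(self.chrom == chrom)[0]

    def chromosomes(self) -> list[int]:
        seen: dict[int, None] = {}
        for c in self.chrom:
            seen.setdefault(int(c), None)
        return list(seen)


@dataclass
class GenotypeDataset:
    """Samples x markers diploid genotype matrix plus metadata."""

    sample_id: list[str]
    population: list[str]
    markers: MarkerMap
    genotypes: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_id), self.markers.n_markers):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_id)} samples x {self.markers.n_markers} markers"
            )
        if len(self.population) != len(self.sample_id):
            raise ValueError("population labels do not match sample count")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2/MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def population_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.population:
            counts[p] = counts.get(p, 0) + 1
        return counts

    def subset_markers(self, index: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            list(self.sample_id),
            list(self.population),
            self.markers.subset(index),
            self.genotypes[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            [self.sample_id[i] for i in index],
            [self.population[i] for i in index],
            self.markers,
            self.genotypes[index, :],
        )

    def dosage(self, marker_index: int) -> np.ndarray:
        """Genotype column as float with NaN for missing calls."""
        col = self.genotypes[:, marker_index].astype(float)
        col[col == MISSING] = np.nan
        return col

    def equals(self, other: "GenotypeDataset", exact_alleles: bool = True) -> bool:
        """Semantic equality.

        With ``exact_alleles=False`` the comparison is orientation-free:
        each marker is re-oriented so that allele A is the lexicographically
        smaller observed allele before comparing, which identifies datasets
        that differ only in which allele was labelled A.
        """
        if (
            self.sample_id != other.sample_id
            or self.population != other.population
            or self.n_markers != other.n_markers
            or list(self.markers.marker_id) != list(other.markers.marker_id)
            or not np.array_equal(self.markers.chrom, other.markers.chrom)
            or not np.array_equal(self.markers.pos_bp, other.markers.pos_bp)
        ):
            return False
        if exact_alleles:
            return (
                list(self.markers.allele_a) == list(other.markers.allele_a)
                and list(self.markers.allele_b) == list(other.markers.allele_b)
                and np.array_equal(self.genotypes, other.genotypes)
            )
        a = _canonical_orientation(self)
        b = _canonical_orientation(other)
        return np.array_equal(a, b)


def _canonical_orientation(ds: GenotypeDataset) -> np.ndarray:
    """Genotypes as sorted allele-letter pairs (None for missing calls).

    This is the orientation-free representation: which allele was labelled
    A/B (and whether an unobserved allele was recorded at all) is erased.
    """
    out = np.empty((ds.n_samples, ds.n_markers), dtype=object)
    for j in range(ds.n_markers):
        a, b = ds.markers.allele_a[j], ds.markers.allele_b[j]
        pairs = {0: (a, a), 1: tuple(sorted((a, b))), 2: (b, b), MISSING: None}
        for i in range(ds.n_samples):
            out[i, j] = pairs[int(ds.genotypes[i, j])]
    return out


@dataclass
class QCReport:
    """Marker-filter accounting; one marker counts at its first failure."""

    n_markers_in: int
    n_markers_out: int
    n_removed_geno: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_prune: int = 0
    geno_max: float = 0.1
    maf_min: float = 0.01
    hwe_p_min: float = 0.01

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_geno
            + self.n_removed_maf
            + self.n_removed_hwe
            + self.n_removed_prune
        )
        if self.n_markers_out != self.n_markers_in - removed:
            raise ValueError("QCReport counts do not reconcile")

    def to_tsv(self) -> str:
        rows = [
            ("n_markers_in", self.n_markers_in),
            ("n_removed_geno", self.n_removed_geno),
            ("n_removed_maf", self.n_removed_maf),
            ("n_removed_hwe", self.n_removed_hwe),
            ("n_removed_prune", self.n_removed_prune),
            ("n_markers_out", self.n_markers_out),
            ("geno_max", self.geno_max),
            ("maf_min", self.maf_min),
            ("hwe_p_min", self.hwe_p_min),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


# ---------------------------------------------------------------------------
# PED/MAP text I/O
# ---------------------------------------------------------------------------


def _read_map_lines(map_source) -> tuple[list[str], list[int], list[int]]:
    ids: list[str] = []
    chroms: list[int] = []
    pos: list[int] = []
    for lineno, line in enumerate(map_source, start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PlinkFormatError(
                f"MAP line {lineno}: expected 4 columns (chrom, id, cM, bp), "
                f"got {len(parts)}"
            )
        chrom_s, marker_id, _cm, bp_s = parts[:4]
        try:
            chrom = int(chrom_s)
        except ValueError as exc:
            raise PlinkFormatError(
                f"MAP line {lineno}: non-numeric chromosome {chrom_s!r}"
            ) from exc
        try:
            bp = int(bp_s)
        except ValueError as exc:
            raise PlinkFormatError(
                f"MAP line {lineno}: non-numeric position {bp_s!r}"
            ) from exc
        ids.append(marker_id)
        chroms.append(chrom)
        pos.append(bp)
    return ids, chroms, pos


def _open_maybe(source, mode="r"):
    if hasattr(source, "read"):
        return source, False
    return open(source, mode), True


def read_plink_text(ped_source, map_source) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    The PED family-ID column is stored as the population label.  Allele A of
    each marker is the first allele observed in sample order (ties within a
    heterozygous first observation broken lexicographically).  ``0 0``
    genotypes become MISSING.  Markers on chromosomes outside 1-29 are
    dropped with a warning.
    """
    fh, close_map = _open_maybe(map_source)
    try:
        ids, chroms, pos = _read_map_lines(fh)
    finally:
        if close_map:
            fh.close()
    n_markers = len(ids)

    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[str]] = []
    fh, close_ped = _open_maybe(ped_source)
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"PED line {lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} MAP markers, got {len(parts)}"
                )
            populations.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    finally:
        if close_ped:
            fh.close()

    n_samples = len(sample_ids)
    if n_samples:
        alleles = np.array(allele_rows, dtype=object)
        a1 = alleles[:, 0::2]
        a2 = alleles[:, 1::2]
    else:
        a1 = np.empty((0, n_markers), dtype=object)
        a2 = np.empty((0, n_markers), dtype=object)

    genotypes = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele_a = np.full(n_markers, "0", dtype=object)
    allele_b = np.full(n_markers, "0", dtype=object)
    for j in range(n_markers):
        c1, c2 = a1[:, j], a2[:, j]
        missing = (c1 == "0") | (c2 == "0")
        obs = np.nonzero(~missing)[0]
        if obs.size == 0:
            continue
        first = obs[0]
        if c1[first] == c2[first]:
            ref = c1[first]
        else:
            ref = min(c1[first], c2[first])
        observed = set(c1[obs]) | set(c2[obs])
        others = sorted(observed - {ref})
        if len(others) > 1:
            raise PlinkFormatError(
                f"marker {ids[j]!r} has more than two alleles: "
                f"{sorted(observed)}"
            )
        alt = others[0] if others else "0"
        allele_a[j] = ref
        allele_b[j] = alt
        code = (c1[obs] != ref).astype(np.int8) + (c2[obs] != ref).astype(np.int8)
        genotypes[obs, j] = code

    markers = MarkerMap(np.array(ids, dtype=object), chroms, pos, allele_a, allele_b)
    ds = GenotypeDataset(sample_ids, populations, markers, genotypes)
    return _drop_non_autosomes(ds)


def _drop_non_autosomes(ds: GenotypeDataset) -> GenotypeDataset:
    keep = np.isin(ds.markers.chrom, list(AUTOSOMES))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d markers on non-autosomal chromosomes", n_drop)
        return ds.subset_markers(np.nonzero(keep)[0])
    return ds


_CODE_TO_PAIR = {0: ("a", "a"), 1: ("a", "b"), 2: ("b", "b")}


def write_plink_text(dataset: GenotypeDataset, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    ped_path = f"{prefix}.ped"
    map_path = f"{prefix}.map"
    m = dataset.markers
    with open(map_path, "w") as fh:
        for j in range(m.n_markers):
            fh.write(f"{m.chrom[j]}\t{m.marker_id[j]}\t0\t{m.pos_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i in range(dataset.n_samples):
            fields = [
                dataset.population[i],
                dataset.sample_id[i],
                "0",
                "0",
                "0",
                "-9",
            ]
            row = dataset.genotypes[i]
            for j in range(m.n_markers):
                g = row[j]
                if g == MISSING:
                    fields.extend(("0", "0"))
                else:
                    pa, pb = _CODE_TO_PAIR[int(g)]
                    fields.append(m.allele_a[j] if pa == "a" else m.allele_b[j])
                    fields.append(m.allele_a[j] if pb == "a" else m.allele_b[j])
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM) read support
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


def read_plink_binary(prefix: str) -> GenotypeDataset:
    """Read a SNP-major PLINK ``.bed/.bim/.fam`` triple."""
    fam_samples: list[str] = []
    fam_pops: list[str] = []
    with open(f"{prefix}.fam") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fam_pops.append(parts[0])
            fam_samples.append(parts[1])
    ids: list[str] = []
    chroms: list[int] = []
    pos: list[int] = []
    aa: list[str] = []
    ab: list[str] = []
    with open(f"{prefix}.bim") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise PlinkFormatError(f"BIM line {lineno}: expected 6 columns")
            chroms.append(int(parts[0]))
            ids.append(parts[1])
            pos.append(int(parts[3]))
            aa.append(parts[4])
            ab.append(parts[5])
    n_samples = len(fam_samples)
    n_markers = len(ids)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkFormatError(
                "BED magic bytes mismatch: not a SNP-major PLINK binary file"
            )
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_marker = (n_samples + 3) // 4
    if data.size != bytes_per_marker * n_markers:
        raise PlinkFormatError(
            f"BED payload is {data.size} bytes; expected "
            f"{bytes_per_marker * n_markers}"
        )
    data = data.reshape(n_markers, bytes_per_marker)
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(n_markers, -1)[:, :n_samples]]
    markers = MarkerMap(np.array(ids, dtype=object), chroms, pos, aa, ab)
    ds = GenotypeDataset(fam_samples, fam_pops, markers, codes.T.copy())
    return _drop_non_autosomes(ds)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _orientation(ra: str, rb: str, da: str, db: str):
    """How to map a dataset's codes onto reference alleles (ra, rb).

    Returns ``(flip, new_rb)`` where ``flip`` means codes 0<->2 and
    ``new_rb`` upgrades a monomorphic reference allele B.  Raises
    ``ValueError`` when the allele sets cannot be reconciled.
    """
    rset = {ra} | ({rb} if rb != "0" else set())
    dset = {da} | ({db} if db != "0" else set())
    if not (dset <= rset or rset <= dset):
        raise ValueError("incompatible")
    if da == ra:
        new_rb = db if rb == "0" and db != "0" else None
        return False, new_rb
    if rb != "0" and da == rb:
        return True, None
    if rb == "0" and db == ra:
        # reference monomorphic in ra; dataset oriented the other way round
        return True, da
    raise ValueError("incompatible")


def merge_populations(datasets: list[GenotypeDataset]) -> GenotypeDataset:
    """Concatenate samples over the marker intersection of all datasets.

    Allele orientation is harmonised by matching allele letters to the first
    dataset: a marker genotyped with alleles swapped has its codes flipped
    0<->2.  Incompatible allele sets raise :class:`MergeError` listing the
    offending markers.
    """
    if len(datasets) < 2:
        raise ValueError("merge requires at least two datasets")
    ref = datasets[0]
    common = set(ref.markers.marker_id)
    for ds in datasets[1:]:
        common &= set(ds.markers.marker_id)
    order = [mid for mid in ref.markers.marker_id if mid in common]
    ref_index = {mid: j for j, mid in enumerate(ref.markers.marker_id)}
    ref_cols = np.array([ref_index[mid] for mid in order], dtype=np.int64)
    merged_map = ref.markers.subset(ref_cols)

    sample_id = list(ref.sample_id)
    population = list(ref.population)
    blocks = [ref.genotypes[:, ref_cols]]
    incompatible: list[str] = []
    for ds in datasets[1:]:
        idx = {mid: j for j, mid in enumerate(ds.markers.marker_id)}
        cols = np.array([idx[mid] for mid in order], dtype=np.int64)
        block = ds.genotypes[:, cols].copy()
        for k, mid in enumerate(order):
            ra, rb = merged_map.allele_a[k], merged_map.allele_b[k]
            da, db = ds.markers.allele_a[cols[k]], ds.markers.allele_b[cols[k]]
            if (da, db) == (ra, rb):
                continue
            try:
                flip, new_rb = _orientation(ra, rb, da, db)
            except ValueError:
                incompatible.append(mid)
                continue
            if flip:
                col = block[:, k]
                nz = col != MISSING
                col[nz] = 2 - col[nz]
            if new_rb is not None:
                merged_map.allele_b[k] = new_rb
        sample_id.extend(ds.sample_id)
        population.extend(ds.population)
        blocks.append(block)
    if incompatible:
        raise MergeError(
            "incompatible allele sets at markers: " + ", ".join(incompatible)
        )
    genotypes = np.vstack(blocks)
    return GenotypeDataset(sample_id, population, merged_map, genotypes)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more probable
    than the observed one (no mid-p adjustment).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("all genotype counts are zero: HWE test undefined")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    valid = common_hom >= 0
    hets, rare_hom, common_hom = hets[valid], rare_hom[valid], common_hom[valid]
    # P(het = h | n, n_rare) via log factorials
    logp = (
        gammaln(n + 1)
        - gammaln(common_hom + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def _missing_fraction(g: np.ndarray) -> np.ndarray:
    return (g == MISSING).sum(axis=0) / g.shape[0]


def _maf(g: np.ndarray) -> np.ndarray:
    """Minor allele frequency per marker over non-missing genotypes."""
    called = g != MISSING
    n_called = called.sum(axis=0)
    dos = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dos / (2.0 * n_called), 0.0)
    return np.minimum(p, 1.0 - p)


def apply_marker_qc(
    dataset: GenotypeDataset,
    geno_max: float = 0.1,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.01,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove markers failing missingness, MAF or HWE filters (in that order)."""
    for name, v in (("geno_max", geno_max), ("maf_min", maf_min), ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    g = dataset.genotypes
    n_in = dataset.n_markers

    keep = _missing_fraction(g) <= geno_max
    n_geno = int((~keep).sum())
    idx = np.nonzero(keep)[0]

    maf = _maf(g[:, idx])
    ok = maf >= maf_min
    n_maf = int((~ok).sum())
    idx = idx[ok]

    hwe_fail = np.zeros(idx.size, dtype=bool)
    for k, j in enumerate(idx):
        col = g[:, j]
        n_aa0 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if n_aa0 + n_het + n_bb == 0:
            continue
        hwe_fail[k] = hwe_exact_test(n_aa0, n_het, n_bb) < hwe_p_min
    n_hwe = int(hwe_fail.sum())
    idx = idx[~hwe_fail]

    out = dataset.subset_markers(idx)
    report = QCReport(
        n_markers_in=n_in,
        n_markers_out=out.n_markers,
        n_removed_geno=n_geno,
        n_removed_maf=n_maf,
        n_removed_hwe=n_hwe,
        geno_max=geno_max,
        maf_min=maf_min,
        hwe_p_min=hwe_p_min,
    )
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise composite r^2 between genotype columns, pairwise-complete."""
    x = g.astype(float)
    x[x == MISSING] = np.nan
    m = x.shape[1]
    mask = ~np.isnan(x)
    xz = np.where(mask, x, 0.0)
    n = mask.T.astype(float) @ mask.astype(float)
    sx = xz.T @ mask.astype(float)
    sy = sx.T
    sxy = xz.T @ xz
    sxx = (xz**2).T @ mask.astype(float)
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r2 = cov**2 / (vx * vy)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def ld_prune(
    dataset: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> GenotypeDataset:
    """Greedy windowed LD pruning.

    Within each sliding window (per chromosome), while any retained pair has
    composite r^2 above ``r2_max``, the member of the worst (highest r^2)
    pair with the lower MAF is removed (ties keep the earlier map position).
    Deterministic for a fixed dataset.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    maf = _maf(dataset.genotypes)
    removed = np.zeros(dataset.n_markers, dtype=bool)
    for chrom in dataset.markers.chromosomes():
        cidx = dataset.markers.chrom_indices(chrom)
        order = np.argsort(dataset.markers.pos_bp[cidx], kind="stable")
        cidx = cidx[order]
        n = cidx.size
        start = 0
        while True:
            win = cidx[start : start + window_snps]
            live = win[~removed[win]]
            if live.size >= 2:
                r2 = _pairwise_r2(dataset.genotypes[:, live])
                while live.size >= 2:
                    iu = np.triu_indices(live.size, k=1)
                    vals = r2[iu]
                    vals = np.where(np.isnan(vals), -1.0, vals)
                    worst = int(np.argmax(vals))
                    if vals[worst] <= r2_max:
                        break
                    a_loc, b_loc = iu[0][worst], iu[1][worst]
                    a, b = live[a_loc], live[b_loc]
                    if maf[a] < maf[b]:
                        drop_loc = a_loc
                    elif maf[b] < maf[a]:
                        drop_loc = b_loc
                    else:
                        # tie: drop the later map position
                        drop_loc = (
                            a_loc
                            if dataset.markers.pos_bp[a] > dataset.markers.pos_bp[b]
                            else b_loc
                        )
                    removed[live[drop_loc]] = True
                    live = np.delete(live, drop_loc)
                    r2 = np.delete(np.delete(r2, drop_loc, axis=0), drop_loc, axis=1)
            if start + window_snps >= n:
                break
            start += step_snps
    keep = np.nonzero(~removed)[0]
    return dataset.subset_markers(keep)
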