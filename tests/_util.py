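"""Shared builders and independent oracles for the test suite.

Oracles here are deliberately naive re-derivations (pure-Python loops,
exact integer arithmetic) kept independent of the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from rohscan import GenotypeDataset, MarkerMap
from rohscan.genotype_io import MISSING


def make_dataset(
    genotypes,
    positions=None,
    chroms=None,
    populations=None,
    sample_ids=None,
    spacing=100_000,
):
    """Build a GenotypeDataset from a genotype matrix with sane defaults."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_markers = g.shape
    if positions is None:
        positions = [1 + j * spacing for j in range(n_markers)]
    if chroms is None:
        chroms = [1] * n_markers
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    if populations is None:
        populations = ["POP"] * n_samples
    markers = MarkerMap(
        np.array([f"m{j}" for j in range(n_markers)], dtype=object),
        chroms,
        positions,
        np.array(["A"] * n_markers, dtype=object),
        np.array(["G"] * n_markers, dtype=object),
    )
    return GenotypeDataset(list(sample_ids), list(populations), markers, g)


# ---------------------------------------------------------------------------
# Hardy-Weinberg enumeration oracle (exact integer weights)
# ---------------------------------------------------------------------------


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Two-sided exact HWE p-value by full enumeration with exact arithmetic.

    The weight of a configuration with h heterozygotes is the number of ways
    to realise it: n! / (nAA! h! naa!) * 2^h; p-values are ratios of exact
    integer weight sums.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa

    def weight(h: int) -> int:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if rare_hom < 0 or common_hom < 0:
            return 0
        return (
            math.factorial(n)
            // (math.factorial(common_hom) * math.factorial(h) * math.factorial(rare_hom))
            * 2**h
        )

    weights = {h: weight(h) for h in range(n_rare % 2, n_rare + 1, 2)}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    tail = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(tail, total)


# ---------------------------------------------------------------------------
# exhaustive sliding-window ROH oracle
# ---------------------------------------------------------------------------


def roh_oracle(genotypes, positions, params):
    """Enumerate every window and candidate stretch with plain loops.

    Returns (fractions, segments) where segments are (start_bp, end_bp,
    n_snps) tuples after the gap/length/count/density filters.
    """
    g = list(genotypes)
    pos = list(positions)
    n = len(g)
    w = params.window_snps
    if n < w:
        return [0.0] * n, []
    fractions = []
    for j in range(n):
        total = 0
        hits = 0
        for s in range(max(0, j - w + 1), min(j, n - w) + 1):
            win = g[s : s + w]
            total += 1
            n_het = sum(1 for x in win if x == 1)
            n_mis = sum(1 for x in win if x == MISSING)
            if n_het <= params.max_het_per_window and n_mis <= params.max_miss_per_window:
                hits += 1
        fractions.append(hits / total)

    candidates = [j for j in range(n) if fractions[j] >= params.window_threshold]
    stretches = []
    current = []
    for j in candidates:
        if current and (
            j != current[-1] + 1 or pos[j] - pos[current[-1]] > params.max_gap_bp
        ):
            stretches.append(current)
            current = []
        current.append(j)
    if current:
        stretches.append(current)

    segments = []
    for stretch in stretches:
        start_bp, end_bp = pos[stretch[0]], pos[stretch[-1]]
        length = end_bp - start_bp + 1
        n_snps = len(stretch)
        if (
            length >= params.min_length_bp
            and n_snps >= params.min_snps_in_run
            and n_snps / length >= params.min_density_snp_per_bp
        ):
            segments.append((start_bp, end_bp, n_snps))
    return fractions, segments


# ---------------------------------------------------------------------------
# naive greedy LD-pruning oracle
# ---------------------------------------------------------------------------


def prune_oracle(dataset, window_snps, step_snps, r2_max):
    """Re-derive the pruning rule with per-pair numpy corrcoef calls."""

    def pair_r2(a, b):
        x = dataset.genotypes[:, a].astype(float)
        y = dataset.genotypes[:, b].astype(float)
        ok = (x != MISSING) & (y != MISSING)
        if ok.sum() < 2:
            return float("nan")
        x, y = x[ok], y[ok]
        if np.all(x == x[0]) or np.all(y == y[0]):
            return float("nan")
        r = np.corrcoef(x, y)[0, 1]
        return r * r

    def maf(a):
        col = dataset.genotypes[:, a]
        called = col != MISSING
        if not called.any():
            return 0.0
        p = col[called].sum() / (2.0 * called.sum())
        return min(p, 1.0 - p)

    removed = set()
    for chrom in dataset.markers.chromosomes():
        cidx = dataset.markers.chrom_indices(chrom)
        cidx = cidx[np.argsort(dataset.markers.pos_bp[cidx], kind="stable")]
        start = 0
        while True:
            window = [int(j) for j in cidx[start : start + window_snps]]
            while True:
                live = [j for j in window if j not in removed]
                best = None
                for ai in range(len(live)):
                    for bi in range(ai + 1, len(live)):
                        r2 = pair_r2(live[ai], live[bi])
                        if not np.isnan(r2) and (best is None or r2 > best[0]):
                            best = (r2, live[ai], live[bi])
                if best is None or best[0] <= r2_max:
                    break
                _, a, b = best
                if maf(a) < maf(b):
                    removed.add(a)
                elif maf(b) < maf(a):
                    removed.add(b)
                else:
                    pa, pb = dataset.markers.pos_bp[a], dataset.markers.pos_bp[b]
                    removed.add(a if pa > pb else b)
            if start + window_snps >= len(cidx):
                break
            start += step_snps
    return [j for j in range(dataset.n_markers) if j not in removed]
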