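import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _util import hwe_oracle, make_dataset, prune_oracle
from rohscan import (
    MISSING,
    GenotypeDataset,
    apply_marker_qc,
    hwe_exact_test,
    ld_prune,
    merge_populations,
    read_plink_binary,
    read_plink_text,
    write_plink_text,
)
from rohscan.genotype_io import MergeError, PlinkFormatError


def _read(ped: str, map_: str) -> GenotypeDataset:
    return read_plink_text(io.StringIO(ped), io.StringIO(map_))


class TestReadPlinkText:
    def test_coding_definition(self):
        ds = _read(
            "FAM1 S1 0 0 0 -9 A A A G\n",
            "1 m1 0 1000\n1 m2 0 2000\n",
        )
        assert ds.genotypes.tolist() == [[0, 1]]
        assert ds.population == ["FAM1"]

    def test_missing_convention(self):
        ds = _read(
            "F S1 0 0 0 -9 A A 0 0\n",
            "1 m1 0 1000\n1 m2 0 2000\n",
        )
        assert ds.genotypes[0, 1] == MISSING

    def test_first_allele_observed_is_allele_a(self):
        ds = _read(
            "F S1 0 0 0 -9 G G\nF S2 0 0 0 -9 A G\n",
            "1 m1 0 1000\n",
        )
        assert ds.markers.allele_a[0] == "G"
        assert ds.genotypes[:, 0].tolist() == [0, 1]

    def test_het_first_tie_breaks_lexicographically(self):
        ds = _read("F S1 0 0 0 -9 G A\n", "1 m1 0 1000\n")
        assert ds.markers.allele_a[0] == "A"
        assert ds.markers.allele_b[0] == "G"

    def test_column_mismatch_names_line(self):
        with pytest.raises(PlinkFormatError, match="PED line 1"):
            _read("F S1 0 0 0 -9 A A\n", "1 m1 0 1000\n1 m2 0 2000\n")

    def test_non_numeric_position(self):
        with pytest.raises(PlinkFormatError, match="position"):
            _read("F S1 0 0 0 -9 A A\n", "1 m1 0 xyz\n")

    def test_non_autosome_dropped(self):
        ds = _read(
            "F S1 0 0 0 -9 A A C C\n",
            "1 m1 0 1000\n30 m2 0 2000\n",
        )
        assert ds.n_markers == 1
        assert list(ds.markers.marker_id) == ["m1"]


class TestWritePlinkText:
    def test_round_trip_fixture(self, tmp_path):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(3, 5)).astype(np.int8)
        g[0, 0] = 0  # first observation defines allele A: keep orientation
        g[1, 2] = MISSING
        ds = make_dataset(g)
        prefix = str(tmp_path / "fx")
        ped, map_ = write_plink_text(ds, prefix)
        back = read_plink_text(ped, map_)
        assert back.equals(ds, exact_alleles=False)

    def test_empty_dataset(self, tmp_path):
        ds = make_dataset(np.empty((0, 0), dtype=np.int8))
        ped, map_ = write_plink_text(ds, str(tmp_path / "empty"))
        assert open(ped).read() == ""
        assert open(map_).read() == ""

    def test_missing_written_as_zero_zero(self, tmp_path):
        ds = make_dataset([[MISSING]])
        ped, _ = write_plink_text(ds, str(tmp_path / "m"))
        assert open(ped).read().split()[-2:] == ["0", "0"]


@st.composite
def datasets(draw):
    n_samples = draw(st.integers(1, 5))
    n_markers = draw(st.integers(1, 8))
    codes = draw(
        st.lists(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=n_markers,
                     max_size=n_markers),
            min_size=n_samples,
            max_size=n_samples,
        )
    )
    return make_dataset(np.array(codes, dtype=np.int8))


@given(datasets())
@settings(max_examples=40, deadline=None)
def test_round_trip_property(tmp_path_factory, ds):
    prefix = str(tmp_path_factory.mktemp("rt") / "d")
    ped, map_ = write_plink_text(ds, prefix)
    back = read_plink_text(ped, map_)
    assert back.equals(ds, exact_alleles=False)


class TestMerge:
    def test_identical_maps_sample_union(self):
        a = make_dataset([[0, 1]], sample_ids=["A1"], populations=["P1"])
        b = make_dataset([[2, 1]], sample_ids=["B1"], populations=["P2"])
        merged = merge_populations([a, b])
        assert merged.sample_id == ["A1", "B1"]
        assert merged.population == ["P1", "P2"]
        assert merged.n_markers == 2

    def test_private_marker_dropped(self):
        a = make_dataset([[0, 1, 2]])
        b = make_dataset([[0, 1]], sample_ids=["T0"])
        b.markers.marker_id[:] = ["m0", "m2"]
        merged = merge_populations([a, b])
        assert sorted(merged.markers.marker_id) == ["m0", "m2"]

    def test_swapped_alleles_flip_codes(self):
        a = make_dataset([[0], [2], [1]])
        b = make_dataset([[2], [0], [1]], sample_ids=["T0", "T1", "T2"])
        b.markers.allele_a[0], b.markers.allele_b[0] = (
            a.markers.allele_b[0],
            a.markers.allele_a[0],
        )
        merged = merge_populations([a, b])
        # same individuals genotyped on both orientations agree after merge
        assert np.array_equal(merged.genotypes[:3], merged.genotypes[3:])

    def test_incompatible_alleles_listed(self):
        a = make_dataset([[1]])
        b = make_dataset([[1]], sample_ids=["T0"])
        b.markers.allele_a[0], b.markers.allele_b[0] = "A", "C"
        with pytest.raises(MergeError, match="m0"):
            merge_populations([a, b])

    def test_commutative_in_content(self):
        rng = np.random.default_rng(5)
        a = make_dataset(rng.integers(0, 3, (4, 6)).astype(np.int8))
        b = make_dataset(
            rng.integers(0, 3, (3, 6)).astype(np.int8),
            sample_ids=["T0", "T1", "T2"],
            populations=["Q"] * 3,
        )
        ab = merge_populations([a, b])
        ba = merge_populations([b, a])
        assert sorted(ab.sample_id) == sorted(ba.sample_id)
        assert sorted(ab.markers.marker_id) == sorted(ba.markers.marker_id)
        for sid in ab.sample_id:
            ia, ib = ab.sample_id.index(sid), ba.sample_id.index(sid)
            cols_a = {m: j for j, m in enumerate(ab.markers.marker_id)}
            cols_b = {m: j for j, m in enumerate(ba.markers.marker_id)}
            for m in ab.markers.marker_id:
                assert ab.genotypes[ia, cols_a[m]] == ba.genotypes[ib, cols_b[m]]


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_balanced_matches_enumeration_oracle(self):
        expected = float(hwe_oracle(25, 50, 25))
        assert hwe_exact_test(25, 50, 25) == pytest.approx(expected, rel=1e-9)

    def test_all_het_matches_oracle_and_fails_qc(self):
        p = hwe_exact_test(0, 100, 0)
        assert p == pytest.approx(float(hwe_oracle(0, 100, 0)), rel=1e-9)
        assert p < 0.01

    def test_all_counts_zero_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_exhaustive_against_oracle_all_n_up_to_50(self):
        for n in range(1, 51):
            for n_aa in range(n + 1):
                for n_het in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_het
                    got = hwe_exact_test(n_aa, n_het, n_bb)
                    want = float(hwe_oracle(n_aa, n_het, n_bb))
                    assert got == pytest.approx(want, rel=1e-8, abs=1e-12), (
                        n_aa,
                        n_het,
                        n_bb,
                    )


class TestMarkerQC:
    def test_missing_fraction_threshold(self):
        g = np.zeros((20, 2), dtype=np.int8)
        g[:10, 0] = 1  # keep marker 0 polymorphic and HWE-unremarkable
        g[:10, 1] = 1
        g[:3, 1] = MISSING  # 0.15 > 0.1
        ds = make_dataset(g)
        out, report = apply_marker_qc(ds)
        assert report.n_removed_geno == 1
        assert out.n_markers == 1

    def test_singleton_allele_removed(self):
        g = np.zeros((86, 1), dtype=np.int8)
        g[0, 0] = 1  # MAC 1 of 172 alleles: MAF ~ 0.0058
        ds = make_dataset(g)
        out, report = apply_marker_qc(ds)
        assert report.n_removed_maf == 1
        assert out.n_markers == 0

    def test_engineered_fixture_counts(self):
        rng = np.random.default_rng(11)
        n_samples, n_markers = 20, 100
        g = np.empty((n_samples, n_markers), dtype=np.int8)
        base = np.array([0] * 5 + [1] * 10 + [2] * 5, dtype=np.int8)  # HWE-ideal
        for j in range(n_markers):
            g[:, j] = rng.permutation(base)
        for j in range(10):  # geno failures
            g[:3, j] = MISSING
        for j in range(10, 20):  # MAF failures (monomorphic)
            g[:, j] = 0
        for j in range(20, 30):  # HWE failures (every sample heterozygous)
            g[:, j] = 1
        ds = make_dataset(g)
        out, report = apply_marker_qc(ds)
        assert report.n_removed_geno == 10
        assert report.n_removed_maf == 10
        assert report.n_removed_hwe == 10
        assert report.n_markers_out == 70
        assert out.n_markers == 70

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.05] = MISSING
        ds = make_dataset(g)
        once, _ = apply_marker_qc(ds)
        twice, report2 = apply_marker_qc(once)
        assert twice.equals(once)
        assert report2.n_markers_in == report2.n_markers_out

    def test_threshold_validation(self):
        ds = make_dataset([[0]])
        with pytest.raises(ValueError):
            apply_marker_qc(ds, geno_max=1.5)


class TestLdPrune:
    def test_duplicated_marker_one_survives(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=10).astype(np.int8)
        g = np.column_stack([col, col])
        ds = make_dataset(g)
        pruned = ld_prune(ds, window_snps=2, step_snps=1)
        assert pruned.n_markers == 1

    def test_independent_markers_untouched(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        ds = make_dataset(g)
        pruned = ld_prune(ds, window_snps=5, step_snps=2, r2_max=0.5)
        assert pruned.n_markers == 10

    def test_toy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        g[:, 4] = g[:, 3]  # correlated triple
        g[:, 5] = np.clip(g[:, 3] + (rng.random(30) < 0.1), 0, 2)
        ds = make_dataset(g)
        pruned = ld_prune(ds, window_snps=6, step_snps=2, r2_max=0.5)
        expected = prune_oracle(ds, window_snps=6, step_snps=2, r2_max=0.5)
        assert [
            list(ds.markers.marker_id).index(m) for m in pruned.markers.marker_id
        ] == expected

    def test_window_validation(self):
        ds = make_dataset([[0, 1]])
        with pytest.raises(ValueError):
            ld_prune(ds, window_snps=1)


class TestPlinkBinary:
    def test_round_trip_via_hand_written_bed(self, tmp_path):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, size=(5, 7)).astype(np.int8)
        g[2, 3] = MISSING
        ds = make_dataset(g)
        prefix = str(tmp_path / "bin")
        # independent writer: pack 2-bit SNP-major codes
        encode = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
        payload = bytearray(b"\x6c\x1b\x01")
        for j in range(ds.n_markers):
            for byte_start in range(0, ds.n_samples, 4):
                byte = 0
                for k, i in enumerate(range(byte_start, min(byte_start + 4, ds.n_samples))):
                    byte |= encode[int(ds.genotypes[i, j])] << (2 * k)
                payload.append(byte)
        with open(f"{prefix}.bed", "wb") as fh:
            fh.write(bytes(payload))
        with open(f"{prefix}.fam", "w") as fh:
            for i in range(ds.n_samples):
                fh.write(f"{ds.population[i]} {ds.sample_id[i]} 0 0 0 -9\n")
        with open(f"{prefix}.bim", "w") as fh:
            m = ds.markers
            for j in range(m.n_markers):
                fh.write(
                    f"{m.chrom[j]}\t{m.marker_id[j]}\t0\t{m.pos_bp[j]}\t"
                    f"{m.allele_a[j]}\t{m.allele_b[j]}\n"
                )
        back = read_plink_binary(prefix)
        assert back.equals(ds)

    def test_bad_magic(self, tmp_path):
        prefix = str(tmp_path / "bad")
        open(f"{prefix}.bed", "wb").write(b"\x00\x00\x00")
        open(f"{prefix}.fam", "w").write("F S 0 0 0 -9\n")
        open(f"{prefix}.bim", "w").write("1\tm\t0\t100\tA\tG\n")
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink_binary(prefix)
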