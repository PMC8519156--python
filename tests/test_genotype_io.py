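"""Genotype I/O and QC filters."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from breedpanel import GenotypeMatrix, MISSING
from breedpanel.errors import EmptyResultError, FormatError, LabelingError
from breedpanel.genotype_io import (
    autosome_filter,
    ibs_duplicate_filter,
    pairwise_ibs,
    qc_filter,
    read_plink,
    read_vcf,
    write_labels,
    write_plink,
    write_vcf,
)

from conftest import random_genotype_matrix


def write_fileset(gm, tmp_path, name="data"):
    prefix = tmp_path / name
    write_plink(gm, prefix)
    write_labels(gm.samples, str(prefix) + ".labels.tsv")
    return prefix


class TestPlink:
    def test_round_trip_identity(self, rng, tmp_path):
        gm = random_genotype_matrix(rng, n_samples=3, n_markers=4, missing_rate=0.2)
        prefix = write_fileset(gm, tmp_path)
        back = read_plink(
            f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam", f"{prefix}.labels.tsv"
        )
        np.testing.assert_array_equal(back.calls, gm.calls)
        assert back.markers["id"].to_list() == gm.markers["id"].to_list()
        assert back.samples.equals(gm.samples)

    def test_round_trip_larger(self, rng, tmp_path):
        gm = random_genotype_matrix(rng, n_samples=13, n_markers=57, missing_rate=0.15)
        prefix = write_fileset(gm, tmp_path)
        back = read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
        np.testing.assert_array_equal(back.calls, gm.calls)

    def test_missing_magic_bytes_rejected(self, rng, tmp_path):
        gm = random_genotype_matrix(rng)
        prefix = write_fileset(gm, tmp_path)
        (tmp_path / "data.bed").write_bytes(b"\x00\x00\x01rubbish")
        with pytest.raises(FormatError, match="magic"):
            read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")

    def test_payload_size_mismatch_rejected(self, rng, tmp_path):
        gm = random_genotype_matrix(rng)
        prefix = write_fileset(gm, tmp_path)
        raw = (tmp_path / "data.bed").read_bytes()
        (tmp_path / "data.bed").write_bytes(raw + b"\x00")
        with pytest.raises(FormatError, match="inconsistent"):
            read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")

    def test_two_bit_decoding_hand_example(self, tmp_path):
        # one marker, four samples packed into a single byte, lowest bits
        # first: 00=hom A1 (dosage 2), 01=missing, 10=het, 11=hom A2
        byte = 0b00 | (0b01 << 2) | (0b10 << 4) | (0b11 << 6)
        (tmp_path / "h.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, byte]))
        (tmp_path / "h.bim").write_text("1\tm1\t0\t100\tA\tB\n")
        (tmp_path / "h.fam").write_text(
            "".join(f"s{i} s{i} 0 0 0 -9\n" for i in range(4))
        )
        gm = read_plink(tmp_path / "h.bed", tmp_path / "h.bim", tmp_path / "h.fam")
        np.testing.assert_array_equal(gm.calls.ravel(), [2, MISSING, 1, 0])

    def test_unknown_sample_in_labels_rejected(self, rng, tmp_path):
        gm = random_genotype_matrix(rng)
        prefix = write_fileset(gm, tmp_path)
        (tmp_path / "bad.tsv").write_text("sample_id\tpopulation\nghost\tH\n")
        with pytest.raises(LabelingError):
            read_plink(
                f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam", tmp_path / "bad.tsv"
            )


class TestVcf:
    def test_round_trip_identity(self, rng, tmp_path):
        gm = random_genotype_matrix(rng, n_samples=5, n_markers=12, missing_rate=0.2)
        path = tmp_path / "data.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        np.testing.assert_array_equal(back.calls, gm.calls)
        assert back.markers["pos"].to_list() == gm.markers["pos"].to_list()

    def test_dosage_and_missing_codes(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/1\t./.\n"
        )
        gm = read_vcf(path)
        np.testing.assert_array_equal(gm.calls.ravel(), [1, MISSING])

    def test_multiallelic_and_non_snp_records_skipped(self, tmp_path):
        records = [
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/0",
            "1\t200\tv2\tA\tG,T\t.\t.\t.\tGT\t0/1",  # multi-allelic
            "1\t300\tv3\tA\tG\t.\t.\t.\tGT\t1/1",
            "1\t400\tv4\tAT\tA\t.\t.\t.\tGT\t0/1",  # indel
            "1\t500\tv5\tC\tT\t.\t.\t.\tGT\t0/1",
        ]
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            + "\n".join(records)
            + "\n"
        )
        gm = read_vcf(path)
        assert gm.markers["id"].to_list() == ["v1", "v3", "v5"]

    def test_vcf_without_gt_rejected(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\tv1\tA\tG\t.\t.\t.\n"
        )
        with pytest.raises(FormatError, match="GT"):
            read_vcf(path)


def make_gm(calls, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": 1000 * (1 + np.arange(m)),
            "a1": "A",
            "a2": "B",
        }
    )
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n)], "population": "P"}
    )
    return GenotypeMatrix.create(calls, markers, samples)


class TestQcFilter:
    def test_complete_matrix_unchanged(self, rng):
        gm = random_genotype_matrix(rng, 10, 10, missing_rate=0.0)
        out = qc_filter(gm, 0.9, 0.9)
        assert out.calls.shape == (10, 10)

    def test_low_call_rate_marker_dropped(self, rng):
        calls = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        calls[:2, 0] = MISSING  # call rate 0.8 at marker 0
        gm = make_gm(calls)
        out = qc_filter(gm, 0.9, 0.9)
        assert "m0" not in out.markers["id"].to_list()
        assert out.n_markers == 9 and out.n_samples == 10

    def test_marker_pass_precedes_sample_pass(self):
        # sample 0 misses only the bad marker: its call rate is exactly
        # 0.9 before marker removal and 1.0 afterwards
        calls = np.ones((4, 10), dtype=np.int8)
        calls[:3, 0] = MISSING  # marker 0 call rate 0.25
        gm = make_gm(calls)
        out = qc_filter(gm, 0.9, 0.9)
        assert out.n_samples == 4 and out.n_markers == 9

    def test_matches_two_pass_oracle(self, rng):
        gm = random_genotype_matrix(rng, 12, 30, missing_rate=0.12)
        out = qc_filter(gm, 0.85, 0.85)
        observed = gm.calls != MISSING
        keep_m = observed.mean(axis=0) > 0.85
        keep_s = observed[:, keep_m].mean(axis=1) > 0.85
        assert out.markers["id"].to_list() == gm.markers["id"][keep_m].to_list()
        assert out.samples["id"].to_list() == gm.samples["id"][keep_s].to_list()

    def test_idempotent(self, rng):
        gm = random_genotype_matrix(rng, 15, 40, missing_rate=0.08)
        once = qc_filter(gm, 0.9, 0.9)
        twice = qc_filter(once, 0.9, 0.9)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_all_markers_removed_is_error(self):
        calls = np.full((4, 3), MISSING, dtype=np.int8)
        calls[0] = 1
        gm = make_gm(calls)
        with pytest.raises(EmptyResultError):
            qc_filter(gm, 0.9, 0.9)


class TestIbsDuplicateFilter:
    def test_duplicated_sample_removed_once(self, rng):
        base = rng.integers(0, 3, size=(1, 100)).astype(np.int8)
        calls = np.vstack([base, rng.integers(0, 3, (1, 100)).astype(np.int8), base])
        gm = make_gm(calls)
        out = ibs_duplicate_filter(gm, 0.98)
        assert out.samples["id"].to_list() == ["s0", "s1"]  # later copy dropped

    def test_boundary_is_exclusive(self):
        # 5 single-dosage differences over 100 markers: IBS = 0.975 <= 0.98
        a = np.ones(100, dtype=np.int8)
        b = a.copy()
        b[:5] = 2
        gm = make_gm(np.vstack([a, b]))
        out = ibs_duplicate_filter(gm, 0.98)
        assert out.n_samples == 2
        out2 = ibs_duplicate_filter(gm, 0.97)  # 0.975 > 0.97 -> duplicate
        assert out2.n_samples == 1

    def test_matches_brute_force_oracle(self, rng):
        gm = random_genotype_matrix(rng, 6, 60, missing_rate=0.1)
        # make two extra near-duplicates
        gm.calls[3] = gm.calls[0]
        gm.calls[5] = gm.calls[2]
        threshold = 0.9
        out = ibs_duplicate_filter(gm, threshold)

        x = gm.calls_float()
        removed = set()
        for i in range(6):
            if i in removed:
                continue
            for j in range(i + 1, 6):
                if j in removed:
                    continue
                both = np.isfinite(x[i]) & np.isfinite(x[j])
                ibs = np.mean(1 - np.abs(x[i][both] - x[j][both]) / 2)
                if ibs > threshold:
                    removed.add(j)
        expected = [f"s{i}" for i in range(6) if i not in removed]
        assert out.samples["id"].to_list() == expected

    def test_no_remaining_pair_above_threshold(self, rng):
        gm = random_genotype_matrix(rng, 8, 50, missing_rate=0.05)
        gm.calls[4] = gm.calls[1]
        out = ibs_duplicate_filter(gm, 0.95)
        ibs = pairwise_ibs(out)
        iu = np.triu_indices(out.n_samples, k=1)
        assert np.all(ibs[iu][np.isfinite(ibs[iu])] <= 0.95)


class TestAutosomeFilter:
    def test_sex_chromosome_removed(self, rng):
        gm = random_genotype_matrix(rng, 4, 6, missing_rate=0)
        gm.markers.loc[2, "chrom"] = "X"
        gm = GenotypeMatrix.create(gm.calls, gm.markers, gm.samples)
        out = autosome_filter(gm)
        assert "X" not in set(out.markers["chrom"])
        assert out.n_markers == 5

    def test_all_autosomal_unchanged(self, rng):
        gm = random_genotype_matrix(rng, 4, 6, missing_rate=0)
        out = autosome_filter(gm)
        assert out.n_markers == 6

    def test_membership_counts(self, rng):
        gm = random_genotype_matrix(rng, 3, 6, missing_rate=0)
        gm.markers["chrom"] = ["1", "29", "30", "MT", "2", "X"]
        gm = GenotypeMatrix.create(gm.calls, gm.markers, gm.samples)
        out = autosome_filter(gm, autosome_labels=[str(i) for i in range(1, 30)])
        assert out.n_markers == 3
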