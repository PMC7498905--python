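"""SNP hard filters, genotype filters, distances, and genet grouping."""

import numpy as np
import pandas as pd
import pytest

from methylradclone.genetics import (
    GenotypeMatrix,
    drop_shared_genotypes,
    genetic_distance,
    genotype_filter,
    group_multilocus_genotypes,
    hard_filter_sites,
    load_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="x">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="x">
##INFO=<ID=DP,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
"""


def info(qd=20, fs=1.0, mq=60, mqrs=0.0, rprs=0.0, dp=300):
    return f"QD={qd};FS={fs};MQ={mq};MQRankSum={mqrs};ReadPosRankSum={rprs};DP={dp}"


def write_vcf(tmp_path, body_lines, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + "\n".join(body_lines) + "\n")
    return path


@pytest.fixture
def hand_vcf(tmp_path):
    """10 hand-built SNPs with a known pass/fail pattern per threshold."""
    g = "GT:GQ:DP"
    ok = "0/1:99:50"
    body = [
        f"chr1\t100\t.\tA\tG\t50\tPASS\t{info()}\t{g}\t{ok}\t{ok}\t0/0:99:50",          # pass
        f"chr1\t200\t.\tA\tG\t50\tPASS\t{info(qd=14.9)}\t{g}\t{ok}\t{ok}\t{ok}",        # fail QD
        f"chr1\t300\t.\tA\tG\t50\tPASS\t{info(fs=12.1)}\t{g}\t{ok}\t{ok}\t{ok}",        # fail FS
        f"chr1\t400\t.\tA\tG\t50\tPASS\t{info(mq=37.9)}\t{g}\t{ok}\t{ok}\t{ok}",        # fail MQ
        f"chr1\t500\t.\tA\tG\t50\tPASS\t{info(mqrs=-1.6)}\t{g}\t{ok}\t{ok}\t{ok}",      # fail MQRankSum
        f"chr1\t600\t.\tA\tG\t50\tPASS\t{info(rprs=-4.1)}\t{g}\t{ok}\t{ok}\t{ok}",      # fail ReadPosRankSum
        f"chr1\t700\t.\tA\tG\t50\tPASS\t{info(dp=5000)}\t{g}\t{ok}\t{ok}\t{ok}",        # fail DP
        f"chr1\t800\t.\tA\tG\t50\tPASS\tQD=20;FS=1;MQ=60;DP=300\t{g}\t{ok}\t{ok}\t1/1:99:50",  # missing rank sums: pass
        f"chr1\t900\t.\tA\tG\t50\tPASS\t{info()}\t{g}\t{ok}\t0/1:29:50\t{ok}",          # pass site, low GQ genotype
        f"chr1\t950\t.\tA\tG,T\t50\tPASS\t{info()}\t{g}\t{ok}\t{ok}\t1/2:99:50",        # triallelic
    ]
    return write_vcf(tmp_path, body)


class TestSiteFilters:
    def test_hand_fixture_survivors(self, hand_vcf):
        records, samples = load_vcf(hand_vcf)
        assert samples == ["A", "B", "C"]
        survivors = {r.pos for r in hard_filter_sites(records)}
        assert survivors == {100, 800, 900, 950}

    def test_single_criterion_failures(self, hand_vcf):
        records, _ = load_vcf(hand_vcf)
        by_pos = {r.pos: r for r in records}
        assert hard_filter_sites([by_pos[700]]) == []  # DP=5000
        assert hard_filter_sites([by_pos[100]]) == [by_pos[100]]

    def test_strict_missing_drops_unannotated(self, hand_vcf):
        records, _ = load_vcf(hand_vcf)
        survivors = {r.pos for r in hard_filter_sites(records, strict_missing=True)}
        assert 800 not in survivors and 100 in survivors

    def test_idempotence(self, hand_vcf):
        records, _ = load_vcf(hand_vcf)
        once = hard_filter_sites(records)
        assert hard_filter_sites(once) == once


class TestGenotypeFilters:
    def test_low_gq_genotype_drops_snp_via_missingness(self, hand_vcf):
        records, samples = load_vcf(hand_vcf)
        gm = genotype_filter(hard_filter_sites(records), samples)
        assert "chr1:900" not in gm.snp_keys

    def test_triallelic_dropped(self, hand_vcf):
        records, samples = load_vcf(hand_vcf)
        gm = genotype_filter(records, samples)
        assert "chr1:950" not in gm.snp_keys

    def test_all_het_maf_half_retained(self, tmp_path):
        ok = "0/1:99:50"
        path = write_vcf(
            tmp_path, [f"chr1\t100\t.\tA\tG\t50\tPASS\t{info()}\tGT:GQ:DP\t{ok}\t{ok}\t{ok}"]
        )
        records, samples = load_vcf(path)
        gm = genotype_filter(records, samples)
        assert gm.snp_keys == ["chr1:100"] and gm.dosages.tolist() == [[1], [1], [1]]

    def test_idempotent_composition(self, hand_vcf):
        records, samples = load_vcf(hand_vcf)
        gm = genotype_filter(hard_filter_sites(records), samples)
        # re-dropping shared genotypes twice equals once
        once = drop_shared_genotypes(gm)
        twice = drop_shared_genotypes(once)
        assert once.snp_keys == twice.snp_keys


class TestSharedGenotypeExclusion:
    def test_uniform_het_dropped_and_variants_kept(self):
        gm = GenotypeMatrix(
            ["a", "b", "c"],
            ["s1", "s2", "s3"],
            np.array([[1, 1, 0], [1, 1, 1], [1, 2, 0]]),
        )
        out = drop_shared_genotypes(gm)
        assert out.snp_keys == ["s2", "s3"]  # s1 column: all 1 across samples?
        # columns: s1=(1,1,1) shared -> dropped; s2=(1,1,2) varies; s3=(0,1,0) varies
        assert out.dosages.shape == (3, 2)

    def test_exact_varying_count(self, rng):
        n, m = 6, 40
        dos = np.ones((n, m), dtype=int)
        vary = rng.choice(m, size=11, replace=False)
        for j in vary:
            dos[int(rng.integers(0, n)), j] = 2
        gm = GenotypeMatrix([f"S{i}" for i in range(n)], [f"s{j}" for j in range(m)], dos)
        assert drop_shared_genotypes(gm).n_snps == 11


class TestDistances:
    def test_identical_rows_distance_zero(self):
        gm = GenotypeMatrix(["x", "y"], ["a", "b"], np.array([[1, 0], [1, 0]]))
        assert genetic_distance(gm).values[0, 1] == 0.0

    def test_four_unit_differences_give_two(self):
        a = np.array([1, 1, 1, 1, 0])
        b = np.array([0, 0, 0, 0, 0])
        gm = GenotypeMatrix(["x", "y"], list("abcde"), np.stack([a, b]))
        assert genetic_distance(gm).values[0, 1] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, rng):
        dos = rng.integers(0, 3, size=(3, 5))
        gm = GenotypeMatrix(["x", "y", "z"], [f"s{j}" for j in range(5)], dos)
        D = genetic_distance(gm).values
        for i in range(3):
            for j in range(3):
                expected = np.sqrt(((dos[i] - dos[j]) ** 2).sum())
                assert D[i, j] == pytest.approx(expected)

    def test_metric_properties(self, rng):
        dos = rng.integers(0, 3, size=(6, 30))
        D = genetic_distance(
            GenotypeMatrix([f"S{i}" for i in range(6)], [f"s{j}" for j in range(30)], dos)
        ).values
        assert np.allclose(D, D.T)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, k] <= D[i, j] + D[j, k] + 1e-9


class TestGenets:
    def test_forty_one_plus_one(self):
        rows = {f"shoot{i}": {"L1": "150/150", "L2": "101/103"} for i in range(41)}
        rows["shoot41"] = {"L1": "147/150", "L2": "101/103"}
        table = pd.DataFrame.from_dict(rows, orient="index")
        genets = group_multilocus_genotypes(table)
        sizes = genets.genet.value_counts()
        assert sorted(sizes.tolist()) == [1, 41]

    def test_all_identical_single_genet(self):
        table = pd.DataFrame.from_dict(
            {f"s{i}": {"L1": "10/12"} for i in range(5)}, orient="index"
        )
        assert group_multilocus_genotypes(table).genet.nunique() == 1

    def test_allele_order_within_locus_irrelevant(self):
        table = pd.DataFrame.from_dict(
            {"a": {"L1": "150/147"}, "b": {"L1": "147/150"}}, orient="index"
        )
        genets = group_multilocus_genotypes(table)
        assert genets.loc["a", "genet"] == genets.loc["b", "genet"]

    def test_missing_locus_unassigned(self):
        table = pd.DataFrame.from_dict(
            {"a": {"L1": "1/2"}, "b": {"L1": None}}, orient="index"
        )
        genets = group_multilocus_genotypes(table)
        assert pd.isna(genets.loc["b", "genet"])
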