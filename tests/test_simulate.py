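"""Ground-truth generators: determinism, planted structure, noise models."""

import numpy as np
import pytest

from methylradclone.digest import ContigSet, enumerate_sites
from methylradclone.genetics import (
    drop_shared_genotypes,
    genetic_distance,
    genotype_filter,
    hard_filter_sites,
    load_vcf,
    GenotypeMatrix,
)
from methylradclone.phenotype import OJIPRecord, compute_piabs
from methylradclone.simulate import (
    ConstructionError,
    SimulationConfig,
    SizingError,
    back_solve_ojip,
    digest_genome,
    generate_genome,
    simulate_bundle,
    simulate_genotypes,
    simulate_methylomes,
    simulate_ojip_linked,
    simulate_reads,
)

SMALL = dict(
    contig_lengths=(6000, 6000, 3000),
    planted_cg_sites=50,
    planted_chg_sites=30,
    n_samples=6,
    n_snps=120,
)


class TestGenome:
    def test_planted_counts_recovered_exactly(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        genome, planted = generate_genome(cfg)
        sites = enumerate_sites(genome, collapse_palindromes=True)
        cg = [s for s in sites if s.motif_class == "CG"]
        chg = [s for s in sites if s.motif_class == "CHG"]
        assert (len(cg), len(chg)) == (50, 30)
        assert {(s.contig, s.start) for s in sites} == {
            (c, p) for c, p, _ in planted
        }

    def test_zero_planted_sites(self):
        cfg = SimulationConfig(
            seed=5, contig_lengths=(2000,), n_contigs=1, chloroplast_index=0,
            planted_cg_sites=0, planted_chg_sites=0,
        )
        genome, _ = generate_genome(cfg)
        assert enumerate_sites(genome) == []

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=9, **SMALL)
        g1, _ = generate_genome(cfg)
        g2, _ = generate_genome(cfg)
        g1.to_fasta(tmp_path / "a.fa")
        g2.to_fasta(tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_infeasible_packing_raises(self):
        with pytest.raises(SizingError):
            generate_genome(
                SimulationConfig(
                    seed=1, contig_lengths=(300,), n_contigs=1,
                    chloroplast_index=0, planted_cg_sites=100, planted_chg_sites=0,
                )
            )


class TestMethylomes:
    def test_chloroplast_rows_all_zero(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        genome, _ = generate_genome(cfg)
        tags = digest_genome(cfg, genome)
        truth = simulate_methylomes(tags, cfg)
        chloro = np.array([t.site.contig == "chloroplast" for t in tags])
        assert chloro.any()
        assert truth.methylome[chloro, :].sum() == 0

    def test_no_epimutation_single_group_identical_methylomes(self):
        cfg = SimulationConfig(
            seed=5, epimutation_rate=0.0,
            group_labels=tuple(["one"] * 6), **SMALL,
        )
        genome, _ = generate_genome(cfg)
        tags = digest_genome(cfg, genome)
        truth = simulate_methylomes(tags, cfg)
        assert (truth.methylome == truth.methylome[:, [0]]).all()
        assert np.allclose(truth.true_epidistance.values, 0.0)

    def test_zero_fp_rate_means_no_chloroplast_reads(self):
        cfg = SimulationConfig(seed=5, fp_emission_rate=0.0, **SMALL)
        genome, _ = generate_genome(cfg)
        tags = digest_genome(cfg, genome)
        truth = simulate_methylomes(tags, cfg)
        reads = simulate_reads(tags, truth, cfg)
        chloro_seqs = {t.sequence for t in tags if t.site.contig == "chloroplast"}
        for sample_reads in reads.values():
            assert all(seq not in chloro_seqs for _, seq in sample_reads)


class TestGenotypes:
    def test_no_somatic_difference_leaves_nothing_after_exclusion(self, tmp_path):
        cfg = SimulationConfig(seed=5, somatic_diff_rate=0.0, **SMALL)
        genome, _ = generate_genome(cfg)
        tags = digest_genome(cfg, genome)
        truth = simulate_methylomes(tags, cfg)
        simulate_genotypes(cfg, truth, tmp_path / "v.vcf")
        records, samples = load_vcf(tmp_path / "v.vcf")
        gm = drop_shared_genotypes(
            genotype_filter(hard_filter_sites(records), samples)
        )
        assert gm.n_snps == 0

    def test_planted_dosages_reproduce_distances(self, tmp_path):
        cfg = SimulationConfig(seed=7, **SMALL)
        genome, _ = generate_genome(cfg)
        tags = digest_genome(cfg, genome)
        truth = simulate_methylomes(tags, cfg)
        gt = simulate_genotypes(cfg, truth, tmp_path / "v.vcf")
        records, samples = load_vcf(tmp_path / "v.vcf")
        gm = drop_shared_genotypes(
            genotype_filter(hard_filter_sites(records), samples)
        )
        # pipeline-recovered SNPs equal the generator's clean differing set
        assert set(gm.snp_keys) == set(gt.columns)
        D = genetic_distance(gm).values
        hand = np.zeros_like(D)
        arr = gt[gm.snp_keys].to_numpy(dtype=float)
        for i in range(len(samples)):
            for j in range(len(samples)):
                hand[i, j] = np.sqrt(((arr[i] - arr[j]) ** 2).sum())
        np.testing.assert_allclose(D, hand, atol=1e-9)


class TestOJIP:
    def test_back_solve_forward_identity(self):
        for target in (0.5, 1.6, 4.8, 7.0):
            f0, f300, fj, fm = back_solve_ojip(target)
            res = compute_piabs(OJIPRecord("s", "L1", 1, f0, f300, fj, fm))
            assert res["PiABS"] == pytest.approx(target, abs=1e-9)

    def test_unreachable_target_raises(self):
        with pytest.raises(ConstructionError):
            back_solve_ojip(0.1)  # demands M0 > 4

    def test_perfect_coupling_yields_high_mantel_r(self, rng):
        from methylradclone.distances import euclidean_distance_matrix
        from methylradclone.mantel import mantel
        from methylradclone.phenotype import (
            performance_difference_matrix,
            read_ojip_tsv,
            shoot_means,
        )

        cfg = SimulationConfig(
            seed=13, mantel_effect=1.0, ojip_noise_sd=0.0, **SMALL
        )
        # colinear configuration: a 1-D phenotype embedding can be lossless
        pts = np.sort(rng.random((6, 1)), axis=0) * 4
        D = euclidean_distance_matrix(pts, [f"S{i:02d}" for i in range(6)], "epi")
        table, true_pi = simulate_ojip_linked(D, cfg)
        means = shoot_means(
            [
                OJIPRecord(str(r.sample_id), str(r.leaf), int(r.replicate),
                           r.F0, r.F300us, r.F2ms, r.FM)
                for r in table.itertuples()
            ]
        )
        np.testing.assert_allclose(
            means["mean_piabs"].to_numpy(), true_pi.to_numpy(), atol=1e-9
        )
        piabs_d = performance_difference_matrix(means)
        res = mantel(D.subset(piabs_d.sample_ids), piabs_d, n_perm=199, seed=0)
        assert res.r_observed == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 200)


class TestBundle:
    def test_bundle_determinism_and_annotation_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=21, **SMALL)
        b1 = simulate_bundle(cfg, tmp_path / "one")
        b2 = simulate_bundle(cfg, tmp_path / "two")
        for name in ("genome.fa", "annotation.gff3", "variants.vcf", "ojip.tsv",
                     "S01.fq"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()
        from methylradclone.annotate import FeatureSet

        fs = FeatureSet.from_gff3(tmp_path / "one" / "annotation.gff3")
        for contig, ivs in b1.genes.items():
            assert sorted(fs.genes.get(contig, [])) == sorted(ivs)
        # TEs land both inside genes and in intergenic space
        te_hits = [
            any(gs <= ts < ge or gs < te <= ge
                for gs, ge in b1.genes.get(contig, []))
            for contig, tes in b1.tes.items()
            for ts, te in tes
        ]
        assert any(te_hits) and not all(te_hits)
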