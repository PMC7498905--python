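"""End-to-end orchestration: digest -> quantify -> annotate -> distances ->
genetics -> phenotype -> Mantel grid -> differential methylation.

A run is a pure function of (input files, parameters, seed); every output
file is hashed into a JSON manifest so reruns are verifiable. Stage
warnings (clipped tags, excluded fluorescence records, unannotated contigs)
are counted in the manifest, never silent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import diffmeth as dm
from . import epidist as ed
from . import genetics as gen
from . import mantel as mt
from . import phenotype as ph
from . import quantify as qt
from .digest import ContigSet, enumerate_sites, extract_tags, write_tag_fasta, write_site_table
from .distances import DistanceMatrix, from_positions


@dataclass
class PipelineConfig:
    genome: str
    gff: str
    reads: dict[str, str]  # sample -> FASTQ path
    vcf: str
    ojip: str
    samples: str  # sample sheet TSV: sample_id, group
    positions: str | None = None
    chloroplast: str = "chloroplast"
    upstream_flank: int = 12
    downstream_flank: int = 16
    max_mismatches: int = 2
    max_ambiguous: int = 1
    seed_length: int = 8
    min_cov: int = 2
    collapse_palindromes: bool = True
    scale_unit_variance: bool = True
    n_perm: int = 1000
    r_min: float = 0.65
    alpha: float = 0.05
    seed: int = 1
    contexts: dict[str, dict[str, str]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.genome, self.gff, self.vcf, self.ojip, self.samples]
        paths += list(self.reads.values())
        if self.positions:
            paths.append(self.positions)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        if self.min_cov < 1 or self.max_mismatches < 0 or self.n_perm < 1:
            raise ValueError("parameter out of range")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {**config.__dict__}, "stages": {}, "warnings": {}}

    # --- digest
    genome = ContigSet.from_fasta(config.genome, chloroplast=config.chloroplast)
    sites = enumerate_sites(
        genome, both_strands=True, collapse_palindromes=config.collapse_palindromes
    )
    tags = extract_tags(sites, genome, config.upstream_flank, config.downstream_flank)
    write_tag_fasta(tags, outdir / "tags.fa")
    write_site_table(sites, outdir / "sites.tsv")
    manifest["stages"]["digest"] = {"n_sites": len(sites), "n_tags": len(tags)}
    manifest["warnings"]["clipped_tags"] = sum(t.clipped for t in tags)

    # --- quantify
    counts = qt.build_count_matrix(
        config.reads,
        tags,
        max_mismatches=config.max_mismatches,
        max_ambiguous=config.max_ambiguous,
        seed_length=config.seed_length,
    )
    counts.to_tsv(outdir / "counts.tsv")
    calls = qt.call_methylation(counts, min_cov=config.min_cov)
    calls.to_frame().to_csv(outdir / "calls.tsv", sep="\t", index_label="site_id")
    classes = [t.motif_class for t in tags]
    chloro_ids = [t.site_id for t in tags if t.site.contig in genome.chloroplast_names]
    fp = qt.estimate_false_positive_rate(
        counts, chloro_ids, min_cov=config.min_cov, motif_classes=classes
    )
    fp.to_csv(outdir / "fp_rates.tsv", sep="\t", index=False)
    rpm = qt.normalize_rpm(counts)
    rpm.to_csv(outdir / "rpm.tsv", sep="\t", index_label="site_id")
    pooled = fp[fp.sample_id == "__pooled__"].set_index("motif_class")["fp_rate_percent"]
    manifest["stages"]["quantify"] = {
        "library_totals": {
            s: int(t) for s, t in zip(counts.sample_ids, counts.library_totals)
        },
        "methylated_sites": int(calls.calls.any(axis=1).sum()),
        "fp_rate_percent": {str(k): float(v) for k, v in pooled.items()},
    }

    # --- annotate
    features = ann.FeatureSet.from_gff3(config.gff)
    contexts = ann.classify_sites(tags, features)
    contexts.to_csv(outdir / "contexts.tsv", sep="\t", index=False)
    summary = ann.summarize_contexts(contexts, calls)
    summary.to_csv(outdir / "context_summary.tsv", sep="\t", index=False)
    manifest["warnings"]["unannotated_contig_sites"] = contexts.attrs[
        "unannotated_contigs"
    ]
    manifest["stages"]["annotate"] = {
        "genic_fraction": float(
            summary.loc[
                (summary.partition == "genic") & (summary.label == "gene"), "fraction"
            ].iloc[0]
        )
        if len(summary)
        else None
    }

    # --- epigenetic distances per context
    epi = ed.context_distances(
        rpm,
        contexts,
        which=config.contexts,
        scale_unit_variance=config.scale_unit_variance,
    )
    for label, D in epi.items():
        D.to_tsv(outdir / f"epidist_{label}.tsv")
    manifest["stages"]["epidist"] = {"contexts": sorted(epi)}

    # --- genetics
    records, vcf_samples = gen.load_vcf(config.vcf)
    hard = gen.hard_filter_sites(records)
    gm = gen.genotype_filter(hard, vcf_samples)
    gm_var = gen.drop_shared_genotypes(gm)
    genetic_d = gen.genetic_distance(gm_var)
    gm_var.to_frame().to_csv(outdir / "dosages.tsv", sep="\t", index_label="sample_id")
    genetic_d.to_tsv(outdir / "genetic_dist.tsv")
    manifest["stages"]["genetics"] = {
        "n_input_snps": len(records),
        "n_hard_filtered": len(hard),
        "n_genotype_filtered": gm.n_snps,
        "n_somatic": gm_var.n_snps,
    }

    # --- phenotype
    ojip_records = ph.read_ojip_tsv(config.ojip)
    per_record = ph.piabs_table(ojip_records)
    per_record.to_csv(outdir / "piabs_records.tsv", sep="\t", index=False)
    means = ph.shoot_means(ojip_records)
    means.to_csv(outdir / "piabs_shoots.tsv", sep="\t")
    piabs_d = ph.performance_difference_matrix(means, label="piabs")
    piabs_d.to_tsv(outdir / "piabs_diff.tsv")
    manifest["warnings"]["excluded_ojip_records"] = int(means["n_excluded"].sum())

    # --- Mantel grid (epi x phenotype | genetic; epi x physical; genetic x ...)
    sample_order = genetic_d.sample_ids
    piabs_aligned = piabs_d.subset([s for s in sample_order if s in piabs_d.sample_ids])
    rows = []
    for label, D in sorted(epi.items()):
        D_sub = D.subset(piabs_aligned.sample_ids)
        gen_sub = genetic_d.subset(piabs_aligned.sample_ids)
        res = mt.partial_mantel(
            D_sub, piabs_aligned, gen_sub, n_perm=config.n_perm, seed=config.seed
        )
        rows.append(
            {
                "x": f"epi_{label}",
                "y": "piabs_diff",
                "conditioned_on": "genetic",
                "r": res.r_observed,
                "p": res.p_value,
            }
        )
    gen_pi = mt.mantel(
        genetic_d.subset(piabs_aligned.sample_ids),
        piabs_aligned,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    rows.append(
        {"x": "genetic", "y": "piabs_diff", "conditioned_on": "", "r": gen_pi.r_observed, "p": gen_pi.p_value}
    )
    if config.positions:
        pos_df = pd.read_csv(config.positions, sep="\t")
        physical = from_positions(
            dict(zip(pos_df.sample_id.astype(str), pos_df.position_m))
        )
        phys_sub = physical.subset(sample_order)
        res = mt.mantel(genetic_d, phys_sub, n_perm=config.n_perm, seed=config.seed)
        rows.append(
            {"x": "genetic", "y": "physical", "conditioned_on": "", "r": res.r_observed, "p": res.p_value}
        )
        for label, D in sorted(epi.items()):
            res = mt.mantel(
                D.subset(sample_order), phys_sub, n_perm=config.n_perm, seed=config.seed
            )
            rows.append(
                {"x": f"epi_{label}", "y": "physical", "conditioned_on": "", "r": res.r_observed, "p": res.p_value}
            )
    grid = pd.DataFrame(rows)
    grid["p_adjusted"] = mt.adjust_bh(grid["p"])
    grid = mt.apply_decision_rule(grid, r_min=config.r_min, alpha=config.alpha)
    grid.to_csv(outdir / "mantel_grid.tsv", sep="\t", index=False)
    manifest["stages"]["mantel"] = {
        "n_tests": len(grid),
        "flagged": grid.loc[grid.linked, ["x", "y"]].to_dict("records"),
    }

    # --- differential methylation between the sample-sheet groups
    sheet = pd.read_csv(config.samples, sep="\t")
    groups = dict(zip(sheet.sample_id.astype(str), sheet.group.astype(str)))
    factors = dm.tmm_factors(counts)
    phi = dm.estimate_common_dispersion(counts, groups, factors)
    results = dm.nb_exact_test(counts, groups, factors, phi, alpha=config.alpha)
    results.to_csv(outdir / "diffmeth.tsv", sep="\t", index=False)
    tally = dm.classify_direction(results, alpha=config.alpha)
    manifest["stages"]["diffmeth"] = {"dispersion": float(phi), **tally}

    # --- manifest
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file()
        and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
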