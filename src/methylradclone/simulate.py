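"""Synthetic study generator with known ground truth.

Emulates the full data constellation of a clonal-meadow methylome study so
every downstream stage is testable without external sequencing data: a
motif-seeded genome whose chloroplast contig is unmethylated, per-sample
binary methylomes with group structure and epimutation noise, Poisson read
depth with a false-positive emission rate from unmethylated sites, a
mostly-shared-heterozygous genotype matrix with somatic differences, and
OJIP fluorescence curves whose PiABS values carry a planted correlation
with methylome distances.

Defaults mirror the emulated study design: 10 shoots in two performance
groups, ~1,000 enzyme target loci at a 59/41 CG/CHG split, a small
chloroplast contig, mean tag depth 10x, a false-positive emission rate
calibrated to a sub-percent chloroplast call rate at 2x coverage, and
somatic differences at 7% of SNPs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from .digest import (
    Contig,
    ContigSet,
    MethylRadTag,
    enumerate_sites,
    extract_tags,
)
from .distances import DistanceMatrix, euclidean_distance_matrix

_MOTIF_SET = ("CCGG", "CCAGG", "CCTGG")  # self-reverse-complement as a set
_BASES = np.array(list("ACGT"))


class SizingError(ValueError):
    """Requested planted sites cannot be packed into the contigs."""


class ConstructionError(ValueError):
    """A back-solved OJIP quadruple cannot reach the requested PiABS."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 3
    contig_lengths: tuple[int, ...] = (40_000, 40_000, 8_000)
    chloroplast_index: int = 2
    planted_cg_sites: int = 590
    planted_chg_sites: int = 410
    n_samples: int = 10
    group_labels: tuple[str, ...] | None = None  # default: half high, half low
    methylation_prob_per_group: dict = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.4}
    )
    epimutation_rate: float = 0.02
    mean_depth: float = 10.0
    fp_emission_rate: float = 0.007
    seq_error_rate: float = 0.0
    n_snps: int = 2_000
    somatic_diff_rate: float = 0.07
    hard_fail_fraction: float = 0.10
    lowq_fraction: float = 0.05
    mantel_effect: float = 0.9
    ojip_noise_sd: float = 0.10
    pi_mean: float = 3.0
    pi_sd: float = 0.8
    upstream_flank: int = 12
    downstream_flank: int = 16
    exclusive_motifs: bool = True
    n_genes: int = 30
    te_fraction: float = 0.30

    def __post_init__(self) -> None:
        if len(self.contig_lengths) != self.n_contigs:
            raise ValueError("contig_lengths length must equal n_contigs")
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig lengths must be positive")
        if not (0 <= self.chloroplast_index < self.n_contigs):
            raise ValueError("chloroplast_index out of range")
        for name in (
            "epimutation_rate",
            "fp_emission_rate",
            "seq_error_rate",
            "somatic_diff_rate",
            "hard_fail_fraction",
            "lowq_fraction",
            "mantel_effect",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def groups(self) -> list[str]:
        if self.group_labels is not None:
            if len(self.group_labels) != self.n_samples:
                raise ValueError("group_labels length must equal n_samples")
            return list(self.group_labels)
        half = self.n_samples // 2
        return ["high"] * half + ["low"] * (self.n_samples - half)

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def meth_prob(self, group: str, mclass: str) -> float:
        table = self.methylation_prob_per_group
        if group in table and isinstance(table[group], dict):
            return float(table[group][mclass])
        return float(table[mclass])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    site_ids: list[str]
    sample_ids: list[str]
    methylome: np.ndarray  # sites x samples, binary
    group_patterns: dict[str, np.ndarray]  # group -> binary site pattern
    true_epidistance: DistanceMatrix
    true_piabs: pd.Series | None = None
    genotype_matrix: pd.DataFrame | None = None
    planted_site_coordinates: list[tuple[str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _scan_motifs(seq: str) -> list[tuple[int, str]]:
    hits = []
    for m in _MOTIF_SET:
        start = seq.find(m)
        while start != -1:
            hits.append((start, m))
            start = seq.find(m, start + 1)
    return sorted(hits)


def _plant_contig(
    rng: np.random.Generator,
    length: int,
    motifs: list[str],
    pad: int,
    exclusive: bool,
) -> tuple[str, list[tuple[int, str]]]:
    """Random contig with the given motifs planted non-overlapping.

    ``pad`` is the flank margin kept motif-free around each planted locus so
    tags never overlap. Accidental motif occurrences are edited away when
    ``exclusive`` (rejection-editing keeps digest counts exactly
    verifiable).
    """
    k = len(motifs)
    slot = pad + 5  # widest motif + spacing
    usable = length - 2 * pad
    if k > 0 and usable < k * slot:
        raise SizingError(
            f"cannot pack {k} motifs into a {length} bp contig "
            f"(needs >= {k * slot + 2 * pad} bp)"
        )
    arr = _random_seq(rng, length)
    planted: list[tuple[int, str]] = []
    if k:
        slack = usable - k * slot
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        order = rng.permutation(k)
        for i, which in enumerate(order):
            pos = pad + int(cuts[i]) + i * slot
            motif = motifs[which]
            arr[pos : pos + len(motif)] = list(motif)
            planted.append((pos, motif))
    planted.sort()
    if exclusive:
        footprints = [(p, p + len(m)) for p, m in planted]
        for _ in range(200):
            seq = "".join(arr)
            dirty = [
                (p, m)
                for p, m in _scan_motifs(seq)
                if (p, p + len(m)) not in set(footprints)
            ]
            if not dirty:
                break
            for p, m in dirty:
                # mutate one base of the accidental occurrence that lies
                # outside every planted footprint
                for off in rng.permutation(len(m)):
                    pos = p + int(off)
                    if not any(s <= pos < e for s, e in footprints):
                        old = arr[pos]
                        choices = [b for b in "ACGT" if b != old]
                        arr[pos] = choices[int(rng.integers(0, 3))]
                        break
        else:  # pragma: no cover - rejection loop virtually always converges
            raise SizingError("could not purge accidental motifs")
    return "".join(arr), planted


def generate_genome(config: SimulationConfig) -> tuple[ContigSet, list[tuple[str, int, str]]]:
    """Random-base contigs with the requested planted CCGG/CCWGG loci.

    Returns the genome and the planted (contig, position, motif) list.
    Sites are distributed across all contigs (including the chloroplast:
    its recognition sites exist; its methylome rows are zero downstream)
    proportionally to length.
    """
    rng = np.random.default_rng(config.seed)
    lengths = np.array(config.contig_lengths, dtype=float)
    weights = lengths / lengths.sum()
    n_cg = config.planted_cg_sites
    n_chg = config.planted_chg_sites
    motifs = ["CCGG"] * n_cg + [
        "CCAGG" if rng.random() < 0.5 else "CCTGG" for _ in range(n_chg)
    ]
    rng.shuffle(motifs)
    counts = rng.multinomial(len(motifs), weights)
    pad = max(config.upstream_flank, config.downstream_flank) + 4
    contigs = []
    planted_all: list[tuple[str, int, str]] = []
    cursor = 0
    for i, length in enumerate(config.contig_lengths):
        name = "chloroplast" if i == config.chloroplast_index else f"contig{i + 1}"
        contig_motifs = motifs[cursor : cursor + counts[i]]
        cursor += counts[i]
        seq, planted = _plant_contig(
            rng, length, contig_motifs, pad, config.exclusive_motifs
        )
        contigs.append(
            Contig(name, seq, is_chloroplast=(i == config.chloroplast_index))
        )
        planted_all.extend((name, pos, m) for pos, m in planted)
    return ContigSet(contigs), planted_all


def generate_annotation(
    genome: ContigSet,
    n_genes: int,
    te_fraction: float,
    seed: int = 0,
    te_length: int = 300,
) -> tuple[dict, dict]:
    """Non-overlapping gene intervals plus TEs inside and between genes.

    Returns (genes, tes) as contig -> [(start, end)] dicts, 0-based
    half-open. TE coverage approximates ``te_fraction`` of each contig, and
    TEs are deliberately placed both within genes and in intergenic space.
    """
    if n_genes < 0 or not (0.0 <= te_fraction <= 1.0):
        raise ValueError("n_genes >= 0 and te_fraction in [0, 1] required")
    rng = np.random.default_rng(seed + 104729)
    lengths = {c.name: len(c.sequence) for c in genome}
    total = sum(lengths.values())
    genes: dict[str, list[tuple[int, int]]] = {c.name: [] for c in genome}
    tes: dict[str, list[tuple[int, int]]] = {c.name: [] for c in genome}
    remaining = n_genes
    names = [c.name for c in genome]
    for idx, name in enumerate(names):
        share = (
            remaining
            if idx == len(names) - 1
            else int(round(n_genes * lengths[name] / total))
        )
        share = min(share, remaining)
        remaining -= share
        if share <= 0:
            continue
        # split the contig into `share` equal slots, one gene per slot
        L = lengths[name]
        slot = L // share
        for s in range(share):
            lo = s * slot
            width = max(50, int(slot * 0.5))
            start = lo + int(rng.integers(0, max(1, slot - width)))
            end = min(L, start + width)
            if end - start >= 10:
                genes[name].append((start, end))
    for name in names:
        L = lengths[name]
        target = int(te_fraction * L)
        covered = 0
        gene_iv = genes[name]
        toggle = True
        guard = 0
        while covered < target and guard < 10_000:
            guard += 1
            length = min(te_length, L)
            if toggle and gene_iv:
                g = gene_iv[int(rng.integers(0, len(gene_iv)))]
                start = g[0] + int(rng.integers(0, max(1, g[1] - g[0] - 10)))
            else:
                start = int(rng.integers(0, max(1, L - length)))
            end = min(L, start + length)
            if end - start < 10:
                continue
            tes[name].append((start, end))
            covered += end - start
            toggle = not toggle
    return genes, tes


# ---------------------------------------------------------------------------
# methylomes and reads


def digest_genome(config: SimulationConfig, genome: ContigSet) -> list[MethylRadTag]:
    """Collapsed (one record per locus) tag set of the synthetic genome."""
    sites = enumerate_sites(genome, both_strands=True, collapse_palindromes=True)
    return extract_tags(
        sites, genome, config.upstream_flank, config.downstream_flank
    )


def simulate_methylomes(
    tags: list[MethylRadTag], config: SimulationConfig
) -> GroundTruth:
    """Per-sample binary methylomes with group structure.

    Each group draws one site-level pattern from its class probabilities;
    each sample inherits its group's pattern and flips every site
    independently with ``epimutation_rate``. Chloroplast rows are forced to
    zero everywhere (the chloroplast genome is unmethylated).
    """
    rng = np.random.default_rng(config.seed + 1)
    site_ids = [t.site_id for t in tags]
    classes = np.array([t.motif_class for t in tags])
    chloro = np.array([t.site.contig == "chloroplast" for t in tags])
    samples = config.sample_ids()
    groups = config.groups()
    patterns: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(groups):
        p = np.where(
            classes == "CG",
            config.meth_prob(g, "CG"),
            config.meth_prob(g, "CHG"),
        )
        pat = (rng.random(len(tags)) < p).astype(np.int8)
        pat[chloro] = 0
        patterns[g] = pat
    methylome = np.zeros((len(tags), len(samples)), dtype=np.int8)
    for j, g in enumerate(groups):
        flips = rng.random(len(tags)) < config.epimutation_rate
        methylome[:, j] = patterns[g] ^ flips.astype(np.int8)
    methylome[chloro, :] = 0
    true_d = euclidean_distance_matrix(methylome.T.astype(float), samples, "true-epi")
    return GroundTruth(
        site_ids=site_ids,
        sample_ids=samples,
        methylome=methylome,
        group_patterns=patterns,
        true_epidistance=true_d,
    )


def _mutate_bases(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_reads(
    tags: list[MethylRadTag],
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Per-sample reads: Poisson depth at methylated sites, a small
    ``fp_emission_rate`` leak from unmethylated sites, optional per-base
    sequencing errors."""
    rng = np.random.default_rng(config.seed + 2)
    out: dict[str, list[tuple[str, str]]] = {}
    for j, sample in enumerate(truth.sample_ids):
        lam = np.where(
            truth.methylome[:, j] == 1,
            config.mean_depth,
            config.mean_depth * config.fp_emission_rate,
        )
        depths = rng.poisson(lam)
        reads = []
        for i, (tag, d) in enumerate(zip(tags, depths)):
            for r in range(int(d)):
                seq = _mutate_bases(rng, tag.sequence, config.seq_error_rate)
                reads.append((f"{sample}:{tag.site_id}:{r}", seq))
        out[sample] = reads
    return out


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# genotypes


_INFO_PASS = {
    "QD": 25.0,
    "FS": 2.0,
    "MQ": 60.0,
    "MQRankSum": 0.5,
    "ReadPosRankSum": 0.5,
    "DP": 800,
}
_INFO_FAIL = {
    "QD": 5.0,
    "FS": 40.0,
    "MQ": 20.0,
    "MQRankSum": -3.0,
    "ReadPosRankSum": -6.0,
    "DP": 6000,
}


def simulate_genotypes(
    config: SimulationConfig, truth: GroundTruth, path: str | Path
) -> pd.DataFrame:
    """Write a VCF of mostly shared-heterozygous SNPs with somatic differences.

    Most SNPs are heterozygous and identical across all ramets (distance to
    the reference genome only); a ``somatic_diff_rate`` fraction differ
    between samples. A ``hard_fail_fraction`` of records violate one
    site-level hard filter each (cycled), and a ``lowq_fraction`` carry one
    low-GQ genotype, so every filter stage has work to do. Returns the
    ground-truth dosage frame (samples x SNPs) of the clean, differing SNPs
    and stores it on ``truth``.
    """
    rng = np.random.default_rng(config.seed + 3)
    samples = truth.sample_ids
    n = len(samples)
    filters = list(_INFO_FAIL)
    rows = []
    clean_keys: list[str] = []
    clean_dosages: list[np.ndarray] = []
    fail_cycle = 0
    for s in range(config.n_snps):
        pos = 1000 + s * 50
        contig = "contig1"
        key = f"{contig}:{pos}"
        differs = rng.random() < config.somatic_diff_rate
        dosage = np.ones(n, dtype=np.int8)
        if differs:
            k = int(rng.integers(1, n))  # 1..n-1 samples carry the variant state
            who = rng.choice(n, size=k, replace=False)
            new_state = 2 if rng.random() < 0.5 else 0
            dosage[who] = new_state
        info = dict(_INFO_PASS)
        fails_hard = rng.random() < config.hard_fail_fraction
        if fails_hard:
            tag = filters[fail_cycle % len(filters)]
            info[tag] = _INFO_FAIL[tag]
            fail_cycle += 1
        gq = np.full(n, 99, dtype=int)
        low_gq = rng.random() < config.lowq_fraction
        if low_gq:
            gq[int(rng.integers(0, n))] = 10
        if differs and not fails_hard and not low_gq:
            clean_keys.append(key)
            clean_dosages.append(dosage.copy())
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = [f"{gts[int(d)]}:{g}:50" for d, g in zip(dosage, gq)]
        info_str = ";".join(
            f"{k2}={v:.2f}" if isinstance(v, float) else f"{k2}={v}"
            for k2, v in info.items()
        )
        rows.append(
            f"{contig}\t{pos}\t.\tA\tG\t100\tPASS\t{info_str}\tGT:GQ:DP\t"
            + "\t".join(fmt)
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=contig1,length=100000000>\n')
        for tag in _INFO_PASS:
            typ = "Integer" if tag == "DP" else "Float"
            fh.write(
                f'##INFO=<ID={tag},Number=1,Type={typ},Description="{tag}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        fh.write("\n".join(rows) + "\n")
    gm = pd.DataFrame(
        np.stack(clean_dosages, axis=1) if clean_dosages else np.zeros((n, 0)),
        index=samples,
        columns=clean_keys,
    )
    truth.genotype_matrix = gm
    return gm


# ---------------------------------------------------------------------------
# phenotype


def back_solve_ojip(
    target_piabs: float, f0: float = 100.0, fm: float = 500.0, vj: float = 0.5
) -> tuple[float, float, float, float]:
    """(F0, F300, FJ, FM) whose PiABS equals ``target_piabs`` exactly.

    The PiABS formula is under-determined, so F0 and FM are anchored
    (arbitrary units) and VJ fixed; M0 then follows. Valid only while the
    implied F300 stays inside (F0, FM).
    """
    span = fm - f0
    factor = (1.0 - f0 / fm) * (span / f0) * (1.0 - vj)  # = PiABS * M0
    m0 = factor / target_piabs
    if not (0.0 < m0 < 4.0):
        raise ConstructionError(
            f"PiABS={target_piabs} unreachable with F0={f0}, FM={fm}, VJ={vj}"
        )
    f300 = f0 + m0 * span / 4.0
    fj = f0 + vj * span
    return f0, f300, fj, fm


def _mds_1d(D: DistanceMatrix) -> np.ndarray:
    """First classical-MDS coordinate of a distance matrix, standardized."""
    d2 = D.values**2
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    coord = vecs[:, -1] * math.sqrt(max(vals[-1], 0.0))
    sd = coord.std()
    if sd == 0:
        return np.zeros(n)
    return (coord - coord.mean()) / sd


def simulate_ojip_linked(
    true_epidistance: DistanceMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """OJIP table whose PiABS differences covary with methylome distances.

    Per-sample targets combine the 1-D MDS embedding of the distance matrix
    (weight ``mantel_effect``) with independent Gaussian noise (weight
    sqrt(1 - mantel_effect^2)); quadruples are back-solved so the computed
    PiABS reproduces each measurement's value exactly. Two pseudo-leaves
    with two replicates each are emitted per shoot, jittered by
    ``ojip_noise_sd``.
    """
    rng = np.random.default_rng(config.seed + 4)
    e = _mds_1d(true_epidistance)
    me = config.mantel_effect
    eps = rng.standard_normal(true_epidistance.n)
    latent = me * e + math.sqrt(max(0.0, 1.0 - me**2)) * eps
    true_pi = np.clip(config.pi_mean + config.pi_sd * latent, 0.5, None)
    rows = []
    for i, sample in enumerate(true_epidistance.sample_ids):
        for leaf in ("L1", "L2"):
            for rep in (1, 2):
                pi_obs = max(0.45, true_pi[i] + rng.normal(0.0, config.ojip_noise_sd))
                f0, f300, fj, fm = back_solve_ojip(pi_obs)
                rows.append(
                    {
                        "sample_id": sample,
                        "leaf": leaf,
                        "replicate": rep,
                        "F0": f0,
                        "F300us": f300,
                        "F2ms": fj,
                        "FM": fm,
                    }
                )
    table = pd.DataFrame(rows)
    return table, pd.Series(true_pi, index=true_epidistance.sample_ids, name="true_piabs")


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genome: ContigSet
    tags: list[MethylRadTag]
    truth: GroundTruth
    reads: dict[str, list[tuple[str, str]]]
    ojip: pd.DataFrame
    genes: dict
    tes: dict
    positions: dict[str, float]
    paths: dict[str, str] = field(default_factory=dict)


def simulate_bundle(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedBundle:
    """Run every generator and (optionally) write the full file bundle."""
    genome, planted = generate_genome(config)
    tags = digest_genome(config, genome)
    truth = simulate_methylomes(tags, config)
    truth.planted_site_coordinates = planted
    reads = simulate_reads(tags, truth, config)
    ojip, true_pi = simulate_ojip_linked(truth.true_epidistance, config)
    truth.true_piabs = true_pi
    genes, tes = generate_annotation(
        genome, config.n_genes, config.te_fraction, seed=config.seed
    )
    positions = {s: 3.0 * i for i, s in enumerate(truth.sample_ids)}

    bundle = SimulatedBundle(
        config, genome, tags, truth, reads, ojip, genes, tes, positions
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(outdir / "genome.fa")
        annotate_mod.write_gff3(
            outdir / "annotation.gff3",
            genes,
            tes,
            {c.name: len(c.sequence) for c in genome},
        )
        for sample, sample_reads in reads.items():
            write_fastq(sample_reads, outdir / f"{sample}.fq")
        simulate_genotypes(config, truth, outdir / "variants.vcf")
        ojip.to_csv(outdir / "ojip.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": list(positions), "position_m": list(positions.values())}
        ).to_csv(outdir / "positions.tsv", sep="\t", index=False)
        sheet = pd.DataFrame(
            {"sample_id": truth.sample_ids, "group": config.groups()}
        )
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        sidecar = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "planted_site_coordinates": [list(p) for p in planted],
            "true_piabs": true_pi.to_dict(),
            "n_sites": len(tags),
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        bundle.paths = {
            "genome": str(outdir / "genome.fa"),
            "gff": str(outdir / "annotation.gff3"),
            "vcf": str(outdir / "variants.vcf"),
            "ojip": str(outdir / "ojip.tsv"),
            "positions": str(outdir / "positions.tsv"),
            "samples": str(outdir / "samples.tsv"),
            "reads": {s: str(outdir / f"{s}.fq") for s in reads},
        }
    # without an outdir the VCF (a file format) is not materialized;
    # call simulate_genotypes() with a path when genotypes are needed
    return bundle
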