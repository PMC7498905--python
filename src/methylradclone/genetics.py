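"""Somatic-SNP filtering, genetic distances, and clonal genotype grouping.

Ramets of one clonal genet are genetically near-identical; the signal of
interest is the small set of SNPs created by somatic mutations. The filter
cascade mirrors the standard GATK-style hard-filtering workflow: site-level
INFO thresholds, then per-genotype quality/depth masking, then biallelic /
minor-allele-frequency / zero-missingness selection, and finally exclusion
of SNPs at which every sample shares the same genotype (those only measure
distance to the reference genome, not among ramets). Euclidean distances
are computed on alternate-allele dosage (0/1/2) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, euclidean_distance_matrix

#: Site-level hard-filter thresholds; a record failing any one is dropped.
HARD_FILTERS = {
    "QD": ("<", 15.0),
    "FS": (">", 12.0),
    "MQ": ("<", 38.0),
    "MQRankSum": ("<", -1.5),
    "ReadPosRankSum": ("<", -4.0),
    "DP": (">", 4000.0),
}

MISSING = -1  # dosage code for a masked genotype


@dataclass
class VariantRecord:
    """One SNP with the INFO annotations and genotypes the filters consume."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple[str, ...]
    info: dict[str, float | None]
    genotypes: list[tuple[int, int] | None]  # allele indices, None = missing
    gq: list[int | None]
    dp: list[int | None]

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}"

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage per sample; MISSING where genotype absent."""
        out = np.full(len(self.genotypes), MISSING, dtype=np.int8)
        for i, gt in enumerate(self.genotypes):
            if gt is not None and -1 not in gt:
                out[i] = sum(1 for a in gt if a > 0)
        return out


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosages with no missing entries."""

    sample_ids: list[str]
    snp_keys: list[str]
    dosages: np.ndarray  # samples x snps

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_keys)):
            raise ValueError("dosage shape mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.snp_keys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_keys)


def load_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Parse SNP records from a VCF 4.x file (plain or bgzipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        info = {}
        for tag in HARD_FILTERS:
            raw = v.INFO.get(tag)
            if raw is None:
                info[tag] = None
            else:
                try:
                    info[tag] = float(raw)
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"unparseable INFO {tag}={raw!r} at {v.CHROM}:{v.POS}"
                    ) from exc
        gts = []
        for g in v.genotypes:
            a = tuple(int(x) for x in g[:-1])
            gts.append(None if -1 in a else a)
        gq = _format_ints(v, "GQ", len(samples))
        dp = _format_ints(v, "DP", len(samples))
        records.append(
            VariantRecord(
                contig=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                info=info,
                genotypes=gts,
                gq=gq,
                dp=dp,
            )
        )
    return records, samples


def _format_ints(v, tag: str, n: int) -> list[int | None]:
    arr = v.format(tag)
    if arr is None:
        return [None] * n
    out = []
    for x in np.asarray(arr).reshape(n, -1)[:, 0]:
        out.append(None if x < 0 else int(x))
    return out


def hard_filter_sites(
    records: Iterable[VariantRecord],
    thresholds: dict[str, tuple[str, float]] = HARD_FILTERS,
    strict_missing: bool = False,
) -> list[VariantRecord]:
    """Drop records failing any site-level threshold.

    A missing annotation does not trigger its criterion (rank-sum tests are
    undefined at sites without heterozygous genotypes); ``strict_missing``
    switches to dropping records with any missing annotation.
    """
    kept = []
    for rec in records:
        fail = False
        for tag, (op, cut) in thresholds.items():
            val = rec.info.get(tag)
            if val is None:
                if strict_missing:
                    fail = True
                    break
                continue
            if (op == "<" and val < cut) or (op == ">" and val > cut):
                fail = True
                break
        if not fail:
            kept.append(rec)
    return kept


def genotype_filter(
    records: Sequence[VariantRecord],
    sample_ids: list[str],
    min_gq: int = 30,
    min_dp: int = 20,
    min_maf: float = 0.01,
) -> GenotypeMatrix:
    """Mask low-quality genotypes, then select clean biallelic SNPs.

    Genotypes with GQ < min_gq or DP < min_dp are set missing; SNPs that are
    not biallelic, have minor allele frequency < min_maf, or retain any
    missing genotype are dropped. Survivors are encoded as alt-allele dosage.
    """
    keys, cols = [], []
    for rec in records:
        if len(rec.alts) != 1:
            continue
        dos = rec.dosages()
        for i in range(len(dos)):
            gq = rec.gq[i]
            dp = rec.dp[i]
            if (gq is not None and gq < min_gq) or (dp is not None and dp < min_dp):
                dos[i] = MISSING
        if np.any(dos == MISSING):
            continue
        p_alt = dos.sum() / (2 * len(dos))
        if min(p_alt, 1 - p_alt) < min_maf:
            continue
        keys.append(rec.key)
        cols.append(dos)
    dosages = (
        np.stack(cols, axis=1) if cols else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(list(sample_ids), keys, dosages)


def drop_shared_genotypes(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only SNPs with >= 2 distinct dosages across samples.

    SNPs at which all ramets share one genotype reflect differences to the
    reference genome only, not somatic variation among ramets.
    """
    if gm.n_snps == 0:
        return gm
    varying = np.array(
        [len(np.unique(gm.dosages[:, j])) > 1 for j in range(gm.n_snps)]
    )
    return GenotypeMatrix(
        list(gm.sample_ids),
        [k for k, v in zip(gm.snp_keys, varying) if v],
        gm.dosages[:, varying],
    )


def genetic_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Euclidean distance between samples in dosage space."""
    if np.any(gm.dosages == MISSING):
        raise ValueError("genotype matrix contains missing entries")
    return euclidean_distance_matrix(
        gm.dosages.astype(float), gm.sample_ids, label="genetic"
    )


def group_multilocus_genotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Group samples sharing an identical multilocus genotype into genets.

    ``table``: one row per sample (index = sample id), one column per locus,
    entries like ``"147/150"`` (allele order within a locus is irrelevant).
    Samples with a missing locus are left unassigned (genet = NA) rather
    than fuzzily matched.
    """
    def norm(cell):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
            return None
        alleles = sorted(str(cell).replace(":", "/").split("/"))
        return "/".join(alleles)

    mlgs: dict[tuple, str] = {}
    out = []
    counter = 0
    for sample, row in table.iterrows():
        normed = tuple(norm(c) for c in row)
        if any(c is None for c in normed):
            out.append({"sample_id": sample, "genet": pd.NA, "mlg": pd.NA})
            continue
        if normed not in mlgs:
            counter += 1
            mlgs[normed] = f"genet{counter}"
        out.append(
            {"sample_id": sample, "genet": mlgs[normed], "mlg": "|".join(normed)}
        )
    return pd.DataFrame(out).set_index("sample_id")
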