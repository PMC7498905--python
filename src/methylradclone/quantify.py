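"""Assign MethylRAD reads uniquely to predicted tags and quantify methylation.

Matching semantics: a read matches a tag if the shorter of the two aligns
ungapped within the longer at some offset with Hamming distance <=
``max_mismatches`` over the overlap, in either orientation. Reads with more
than ``max_ambiguous`` N bases are discarded before anything else. A read is
counted only if a single site achieves the minimum distance and every other
matching site exceeds it (uniquely mapped). An 8-mer seed index accelerates
candidate lookup; for overlaps shorter than three seed lengths the search
falls back to an exhaustive scan so the seed can never change results.

Methylation calls require >= ``min_cov`` reads at a site. The false-positive
rate of the protocol is estimated from the chloroplast genome, which is
essentially unmethylated in plants, as the percentage of chloroplast sites
that would nevertheless be called methylated.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .digest import MethylRadTag, revcomp


@dataclass
class TagCountMatrix:
    """Raw per-site read counts (sites x samples) with library totals."""

    site_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_totals: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_totals = np.asarray(self.library_totals, dtype=np.int64)
        if self.counts.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match site/sample ids")
        if len(self.library_totals) != len(self.sample_ids):
            raise ValueError("library_totals length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts.sum(axis=0) > self.library_totals):
            raise ValueError("column sums exceed library totals")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.site_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# library_totals\t" + "\t".join(map(str, self.library_totals)) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, path) -> "TagCountMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# library_totals"):
                raise ValueError("missing library_totals header line")
            totals = np.array([int(x) for x in header.strip().split("\t")[1:]])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(), totals)


@dataclass
class MethylationCallMatrix:
    site_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    min_cov: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.site_ids, columns=self.sample_ids)


class MalformedFastqError(ValueError):
    pass


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file (gzip allowed)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(qual) != len(seq):
                raise MalformedFastqError(f"malformed FASTQ record {header.strip()!r} in {path}")
            yield header[1:].split()[0], seq.upper()


class TagIndex:
    """Seed index over tags for containment matching.

    The index maps every ``seed_length``-mer of every tag to (tag, position)
    pairs; a read/tag pair with at most ``max_mismatches`` mismatches over an
    overlap of at least 3 x seed_length necessarily shares an aligned exact
    seed (pigeonhole over three seed-sized blocks), so seed lookup plus
    verification is exact there. Shorter overlaps are handled exhaustively.
    """

    def __init__(self, tags: Sequence[MethylRadTag], seed_length: int = 8):
        if not tags:
            raise ValueError("empty tag set")
        self.seed_length = seed_length
        self.tags = list(tags)
        self.site_ids = [t.site_id for t in tags]
        self.sequences = [t.sequence for t in tags]
        self.min_tag_len = min(len(s) for s in self.sequences)
        self.max_tag_len = max(len(s) for s in self.sequences)
        self.uniform_length = self.min_tag_len == self.max_tag_len
        self.seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i, seq in enumerate(self.sequences):
            for pos in range(len(seq) - seed_length + 1):
                self.seeds[seq[pos : pos + seed_length]].append((i, pos))
        self.exact: dict[str, set[int]] = defaultdict(set)
        for i, seq in enumerate(self.sequences):
            self.exact[seq].add(i)


def _pair_min_distance(read: str, tag: str, max_mm: int) -> int | None:
    """Min Hamming distance over all containment offsets, or None if > max_mm."""
    short, long_ = (read, tag) if len(read) <= len(tag) else (tag, read)
    ls, ll = len(short), len(long_)
    best: int | None = None
    for off in range(ll - ls + 1):
        d = 0
        window = long_[off : off + ls]
        for a, b in zip(short, window):
            if a != b:
                d += 1
                if best is not None and d >= best:
                    break
                if d > max_mm:
                    break
        else:
            if best is None or d < best:
                best = d
                if best == 0:
                    return 0
        continue
    if best is not None and best <= max_mm:
        return best
    return None


def _candidates(index: TagIndex, oriented_read: str) -> set[int]:
    k = index.seed_length
    cands: set[int] = set()
    for pos in range(len(oriented_read) - k + 1):
        for tag_i, _ in index.seeds.get(oriented_read[pos : pos + k], ()):
            cands.add(tag_i)
    return cands


def match_read(index: TagIndex, read: str, max_mismatches: int = 2) -> dict[int, int]:
    """Best distance per tag index over both orientations; only hits <= max_mm."""
    hits: dict[int, int] = {}
    for oriented in (read, revcomp(read)):
        overlap = min(len(oriented), index.min_tag_len)
        if overlap >= 3 * index.seed_length:
            cand = _candidates(index, oriented)
        else:
            cand = set(range(len(index.sequences)))
        for tag_i in cand:
            d = _pair_min_distance(oriented, index.sequences[tag_i], max_mismatches)
            if d is not None and (tag_i not in hits or d < hits[tag_i]):
                hits[tag_i] = d
    return hits


def match_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    tags: Sequence[MethylRadTag],
    max_mismatches: int = 2,
    max_ambiguous: int = 1,
    seed_length: int = 8,
) -> tuple[np.ndarray, int]:
    """Count uniquely matching reads per tag.

    Returns (counts aligned to ``tags`` order, library total). The library
    total is the number of reads surviving the N filter, whether or not they
    matched (the normalization basis for reads-per-million).
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    index = TagIndex(tags, seed_length=seed_length)
    counts = np.zeros(len(tags), dtype=np.int64)
    library_total = 0
    for _name, seq in reads:
        if seq.count("N") > max_ambiguous:
            continue
        library_total += 1
        # fast path: when every tag has the same length as the read,
        # containment degenerates to full-length equality, so a distance-0
        # competitor would be sequence-identical and share the dict entry --
        # uniqueness within the exact lookup is then exact
        if index.uniform_length and len(seq) == index.min_tag_len:
            exact_sites = set(index.exact.get(seq, ())) | set(
                index.exact.get(revcomp(seq), ())
            )
            if len(exact_sites) == 1:
                counts[exact_sites.pop()] += 1
                continue
            if len(exact_sites) > 1:
                continue  # distance-0 multi-mapper
        hits = match_read(index, seq, max_mismatches=max_mismatches)
        if not hits:
            continue
        best = min(hits.values())
        winners = {
            index.site_ids[i] for i, d in hits.items() if d == best
        }
        if len(winners) == 1:
            best_tags = [i for i, d in hits.items() if d == best]
            counts[best_tags[0]] += 1
    return counts, library_total


def build_count_matrix(
    sample_reads: dict[str, Iterable[tuple[str, str]] | str | Path],
    tags: Sequence[MethylRadTag],
    **kwargs,
) -> TagCountMatrix:
    site_ids = [t.site_id for t in tags]
    sample_ids = list(sample_reads)
    counts = np.zeros((len(tags), len(sample_ids)), dtype=np.int64)
    totals = np.zeros(len(sample_ids), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        col, total = match_reads(sample_reads[sample], tags, **kwargs)
        counts[:, j] = col
        totals[j] = total
    return TagCountMatrix(site_ids, sample_ids, counts, totals)


def call_methylation(counts: TagCountMatrix, min_cov: int = 2) -> MethylationCallMatrix:
    """Binary calls: methylated iff raw count >= min_cov."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return MethylationCallMatrix(
        list(counts.site_ids),
        list(counts.sample_ids),
        (counts.counts >= min_cov).astype(np.int8),
        min_cov,
    )


def methylation_summary(
    calls: MethylationCallMatrix, motif_classes: Sequence[str]
) -> pd.DataFrame:
    """Per-sample and overall methylated-site counts with the CG/CHG split."""
    classes = np.asarray(motif_classes)
    rows = []
    for j, sample in enumerate(calls.sample_ids):
        col = calls.calls[:, j].astype(bool)
        rows.append(
            {
                "sample_id": sample,
                "methylated_sites": int(col.sum()),
                "CG": int((col & (classes == "CG")).sum()),
                "CHG": int((col & (classes == "CHG")).sum()),
            }
        )
    any_meth = calls.calls.any(axis=1)
    rows.append(
        {
            "sample_id": "__all__",
            "methylated_sites": int(any_meth.sum()),
            "CG": int((any_meth & (classes == "CG")).sum()),
            "CHG": int((any_meth & (classes == "CHG")).sum()),
        }
    )
    return pd.DataFrame(rows)


def estimate_false_positive_rate(
    counts: TagCountMatrix,
    chloroplast_site_ids: Sequence[str],
    min_cov: int = 2,
    motif_classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percent of chloroplast sites called methylated, per class and pooled.

    The chloroplast genome is essentially unmethylated, so any chloroplast
    site with >= min_cov reads is a false positive of the protocol.
    """
    chloro = set(chloroplast_site_ids)
    if not chloro:
        raise ValueError("empty chloroplast site set")
    mask = np.array([s in chloro for s in counts.site_ids])
    if not mask.any():
        raise ValueError("no chloroplast sites present in the count matrix")
    classes = (
        np.asarray(motif_classes)
        if motif_classes is not None
        else np.array(["all"] * len(counts.site_ids))
    )
    rows = []
    samples = list(counts.sample_ids) + ["__pooled__"]
    for mclass in list(dict.fromkeys(classes[mask])) + ["all"]:
        cmask = mask if mclass == "all" else (mask & (classes == mclass))
        n_sites = int(cmask.sum())
        if n_sites == 0:
            continue
        for sample in samples:
            if sample == "__pooled__":
                called = int((counts.counts[cmask, :] >= min_cov).sum())
                denom = n_sites * len(counts.sample_ids)
            else:
                j = counts.sample_ids.index(sample)
                called = int((counts.counts[cmask, j] >= min_cov).sum())
                denom = n_sites
            rows.append(
                {
                    "sample_id": sample,
                    "motif_class": mclass,
                    "min_cov": min_cov,
                    "n_chloroplast_sites": n_sites,
                    "n_called": called,
                    "fp_rate_percent": 100.0 * called / denom,
                }
            )
    return pd.DataFrame(rows)


def normalize_rpm(counts: TagCountMatrix) -> pd.DataFrame:
    """Reads-per-million: count / library_total x 1e6 (sites x samples)."""
    zero = [s for s, t in zip(counts.sample_ids, counts.library_totals) if t == 0]
    if zero:
        raise ValueError(f"zero library total for sample(s): {', '.join(zero)}")
    rpm = counts.counts / counts.library_totals[None, :] * 1e6
    return pd.DataFrame(rpm, index=counts.site_ids, columns=counts.sample_ids)
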