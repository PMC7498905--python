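"""In-silico FspEI digestion: predict MethylRAD tags from a genome.

FspEI is a methylation-dependent restriction enzyme that recognizes fully
methylated CCGG (CG context) and CCWGG (CHG context, W = A or T) motifs and
cleaves both strands a fixed distance (N12/N16) 3' of the modified cytosine,
releasing ~32 bp fragments. A MethylRAD library therefore only contains
fragments from methylated recognition sites; predicting every potential
site in the reference genome yields the tag set that sequenced reads are
assigned to.

Coordinates are 0-based half-open internally; 1-based only at FASTA-header
and GFF3 boundaries.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default recognition motifs; IUPAC W expands to A/T.
DEFAULT_MOTIFS = ("CCGG", "CCWGG")

_IUPAC = {"W": "AT", "A": "A", "C": "C", "G": "G", "T": "T"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expand_motif(motif: str) -> list[str]:
    """Expand IUPAC ambiguity codes (only W needed here) to concrete motifs."""
    out = [""]
    for base in motif.upper():
        if base not in _IUPAC:
            raise ValueError(f"unsupported motif base {base!r} in {motif!r}")
        out = [prefix + b for prefix in out for b in _IUPAC[base]]
    return out


def motif_class(motif_text: str) -> str:
    """CG iff the motif is CCGG, otherwise CHG."""
    return "CG" if motif_text == "CCGG" else "CHG"


@dataclass(frozen=True)
class Contig:
    name: str
    sequence: str
    is_chloroplast: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        extra = set(self.sequence) - set("ACGTN")
        if extra:
            raise ValueError(f"contig {self.name}: invalid characters {extra}")


@dataclass
class ContigSet:
    """Ordered reference contigs, one optionally flagged as the chloroplast."""

    contigs: list[Contig]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig identifiers are not unique")

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def get(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def chloroplast_names(self) -> set[str]:
        return {c.name for c in self.contigs if c.is_chloroplast}

    @classmethod
    def from_fasta(
        cls, path: str | Path, chloroplast: str | None = None
    ) -> "ContigSet":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(
            [
                Contig(r.id, str(r.seq), is_chloroplast=(r.id == chloroplast))
                for r in records
            ]
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(c.sequence), id=c.name, description="")
            for c in self.contigs
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True, order=True)
class RecognitionSite:
    """One motif occurrence; ``start`` is the forward-strand footprint start."""

    contig: str
    start: int
    strand: str
    motif_class: str = field(compare=False)
    motif_text: str = field(compare=False)

    @property
    def site_id(self) -> str:
        return f"{self.contig}:{self.start}:{self.strand}"

    @property
    def footprint(self) -> tuple[int, int]:
        return self.start, self.start + len(self.motif_text)

    @property
    def anchor(self) -> int:
        """Forward-strand position of the modified (second) cytosine."""
        if self.strand == "+":
            return self.start + 1
        return self.start + len(self.motif_text) - 2


@dataclass(frozen=True)
class MethylRadTag:
    site: RecognitionSite
    tag_start: int
    tag_end: int
    sequence: str
    clipped: bool = False

    @property
    def site_id(self) -> str:
        return self.site.site_id

    @property
    def motif_class(self) -> str:
        return self.site.motif_class


def enumerate_sites(
    genome: ContigSet,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    both_strands: bool = True,
    collapse_palindromes: bool = False,
) -> list[RecognitionSite]:
    """Find every recognition-motif occurrence in the genome.

    Occurrences on the minus strand are reported at the forward-strand
    coordinates of their footprint, with ``motif_text`` as read on the minus
    strand. Overlapping occurrences are all reported. Candidate windows
    containing N are skipped (a motif call requires unambiguous bases).

    With ``collapse_palindromes`` the two strand-symmetric records of one
    locus (CCGG with itself; CCAGG with the CCTGG it implies on the other
    strand) merge into the plus-strand record.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    concrete: list[str] = []
    for m in motifs:
        concrete.extend(expand_motif(m))
    # dedupe, keep order
    concrete = list(dict.fromkeys(concrete))

    sites: list[RecognitionSite] = []
    for contig in genome:
        seq = contig.sequence
        for m in concrete:
            pattern = re.compile(f"(?={re.escape(m)})")
            for match in pattern.finditer(seq):
                sites.append(
                    RecognitionSite(contig.name, match.start(), "+", motif_class(m), m)
                )
            if both_strands:
                # m on the minus strand appears as revcomp(m) on the forward
                # strand; footprint coordinates are those of the forward match
                rc = revcomp(m)
                pattern_rc = re.compile(f"(?={re.escape(rc)})")
                for match in pattern_rc.finditer(seq):
                    sites.append(
                        RecognitionSite(
                            contig.name, match.start(), "-", motif_class(m), m
                        )
                    )

    if collapse_palindromes:
        seen: dict[tuple[str, int, int], RecognitionSite] = {}
        for s in sites:
            key = (s.contig, s.start, len(s.motif_text))
            prev = seen.get(key)
            if prev is None or (prev.strand == "-" and s.strand == "+"):
                seen[key] = s
        sites = list(seen.values())

    order = {c.name: i for i, c in enumerate(genome)}
    sites.sort(key=lambda s: (order[s.contig], s.start, s.strand))
    return sites


def extract_tags(
    sites: Iterable[RecognitionSite],
    genome: ContigSet,
    upstream_flank: int = 12,
    downstream_flank: int = 16,
) -> list[MethylRadTag]:
    """Cut one tag per site: flanks are relative to the motif on its strand.

    Minus-strand tags report the reverse-complement sequence over the
    forward-strand footprint interval. Tags truncated at a contig edge are
    flagged ``clipped``.
    """
    if upstream_flank < 0 or downstream_flank < 0:
        raise ValueError("flanks must be nonnegative")
    tags = []
    for site in sites:
        contig = genome.get(site.contig)
        length = len(contig.sequence)
        m_start, m_end = site.footprint
        if site.strand == "+":
            want_start = m_start - upstream_flank
            want_end = m_end + downstream_flank
        else:
            want_start = m_start - downstream_flank
            want_end = m_end + upstream_flank
        start = max(0, want_start)
        end = min(length, want_end)
        seq = contig.sequence[start:end]
        if site.strand == "-":
            seq = revcomp(seq)
        tags.append(
            MethylRadTag(
                site=site,
                tag_start=start,
                tag_end=end,
                sequence=seq,
                clipped=(start != want_start or end != want_end),
            )
        )
    return tags


def write_tag_fasta(tags: Iterable[MethylRadTag], path: str | Path) -> None:
    """Headers: ``>site_id|motif_class|tag_start-tag_end|clipped={0,1}``."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(
                f">{t.site_id}|{t.motif_class}|{t.tag_start}-{t.tag_end}"
                f"|clipped={int(t.clipped)}\n{t.sequence}\n"
            )


def read_tag_fasta(path: str | Path) -> list[MethylRadTag]:
    tags = []
    for record in SeqIO.parse(str(path), "fasta"):
        site_id, mclass, interval, clipped = record.id.split("|")
        contig, start, strand = site_id.rsplit(":", 2)
        tag_start, tag_end = (int(x) for x in interval.split("-"))
        motif_text = "CCGG" if mclass == "CG" else "CCAGG"
        # motif_text for CHG sites is not recoverable from the class alone;
        # recover it from the tag sequence instead (motif sits after the
        # upstream flank on the tag's own strand)
        seq = str(record.seq)
        site = RecognitionSite(contig, int(start), strand, mclass, motif_text)
        if mclass == "CHG":
            for cand in ("CCAGG", "CCTGG"):
                off = _motif_offset(site, int(start), int(tag_start), int(tag_end))
                if seq[off : off + 5] == cand:
                    site = RecognitionSite(contig, int(start), strand, mclass, cand)
                    break
        tags.append(
            MethylRadTag(
                site=site,
                tag_start=tag_start,
                tag_end=tag_end,
                sequence=seq,
                clipped=clipped == "clipped=1",
            )
        )
    return tags


def _motif_offset(site: RecognitionSite, start: int, tag_start: int, tag_end: int) -> int:
    motif_len = 5 if site.motif_class == "CHG" else 4
    if site.strand == "+":
        return start - tag_start
    return tag_end - (start + motif_len)


def write_site_table(sites: Iterable[RecognitionSite], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "contig": s.contig,
                "start": s.start,
                "strand": s.strand,
                "motif_class": s.motif_class,
                "motif_text": s.motif_text,
                "anchor": s.anchor,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)
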