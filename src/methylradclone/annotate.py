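"""Genomic-context classification of methylation sites.

Each site is placed on two independent axes from the GFF3 annotation:
gene vs intergenic, and TE vs non-TE (transposable elements occur both
inside genes and in intergenic space). Together with the CG/CHG motif class
this yields the sequence contexts the downstream distance and differential
analyses are stratified by.

A site's position is its anchor: the modified (second) cytosine of the
recognition motif, in forward-strand coordinates. GFF3 intervals are
1-based inclusive and converted to 0-based half-open on parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .digest import MethylRadTag
from .quantify import MethylationCallMatrix

#: RepeatModeler de-novo family naming used to recognize TE features.
DEFAULT_TE_PATTERN = r"rnd-[1-5]"


@dataclass
class FeatureSet:
    """Gene and TE intervals per contig, 0-based half-open."""

    genes: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    tes: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._gene_trees = {
            c: IntervalTree.from_tuples((s, e) for s, e in iv if e > s)
            for c, iv in self.genes.items()
        }
        self._te_trees = {
            c: IntervalTree.from_tuples((s, e) for s, e in iv if e > s)
            for c, iv in self.tes.items()
        }

    def contigs(self) -> set[str]:
        return set(self.genes) | set(self.tes)

    def is_genic(self, contig: str, pos: int) -> bool:
        tree = self._gene_trees.get(contig)
        return bool(tree and tree.overlaps(pos))

    def is_te(self, contig: str, pos: int) -> bool:
        tree = self._te_trees.get(contig)
        return bool(tree and tree.overlaps(pos))

    @classmethod
    def from_gff3(
        cls, path: str | Path, te_pattern: str = DEFAULT_TE_PATTERN
    ) -> "FeatureSet":
        """Parse genes (type ``gene``) and TE features.

        A feature counts as a TE if its source column, type, or any
        attribute value matches ``te_pattern`` (RepeatModeler round-N family
        names by default).
        """
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        te_re = re.compile(te_pattern)
        genes: dict[str, list[tuple[int, int]]] = {}
        tes: dict[str, list[tuple[int, int]]] = {}
        for feat in db.all_features():
            interval = (feat.start - 1, feat.end)  # GFF3 1-based inclusive
            attr_text = ";".join(
                f"{k}={','.join(v)}" for k, v in sorted(feat.attributes.items())
            )
            if feat.featuretype == "gene":
                genes.setdefault(feat.seqid, []).append(interval)
            if (
                te_re.search(feat.source or "")
                or te_re.search(feat.featuretype or "")
                or te_re.search(attr_text)
            ):
                tes.setdefault(feat.seqid, []).append(interval)
        return cls(genes=genes, tes=tes)


def classify_sites(
    tags: Sequence[MethylRadTag], features: FeatureSet
) -> pd.DataFrame:
    """One row per site: site_id, genic, te, motif_class, context.

    Sites on contigs absent from the annotation classify intergenic/non-TE;
    their number is reported in the frame's ``attrs['unannotated_contigs']``
    warning counter.
    """
    known = features.contigs()
    rows = []
    unannotated = 0
    for tag in tags:
        site = tag.site
        if site.contig not in known:
            unannotated += 1
        genic = features.is_genic(site.contig, site.anchor)
        te = features.is_te(site.contig, site.anchor)
        rows.append(
            {
                "site_id": tag.site_id,
                "genic": "gene" if genic else "intergenic",
                "te": "TE" if te else "non-TE",
                "motif_class": site.motif_class,
            }
        )
    df = pd.DataFrame(rows, columns=["site_id", "genic", "te", "motif_class"])
    if len(df):
        df["context"] = df["genic"] + "-" + df["te"] + "-" + df["motif_class"]
    else:
        df["context"] = pd.Series(dtype=str)
    df.attrs["unannotated_contigs"] = unannotated
    return df


def summarize_contexts(
    contexts: pd.DataFrame, calls: MethylationCallMatrix
) -> pd.DataFrame:
    """Context proportions among sites methylated in at least one sample.

    Reports the genic/intergenic split, the TE fraction within each genic
    class, and the CG fraction overall and within each genic class. Returns
    an empty frame when nothing is methylated.
    """
    meth_sites = {
        s for s, any_call in zip(calls.site_ids, calls.calls.any(axis=1)) if any_call
    }
    sub = contexts[contexts["site_id"].isin(meth_sites)]
    if sub.empty:
        return pd.DataFrame(columns=["partition", "label", "fraction", "n"])
    rows = []
    total = len(sub)
    for label in ("gene", "intergenic"):
        part = sub[sub["genic"] == label]
        rows.append(
            {"partition": "genic", "label": label, "fraction": len(part) / total, "n": len(part)}
        )
        if len(part):
            for te_label in ("TE", "non-TE"):
                k = (part["te"] == te_label).sum()
                rows.append(
                    {
                        "partition": f"te_within_{label}",
                        "label": te_label,
                        "fraction": k / len(part),
                        "n": int(k),
                    }
                )
            for mclass in ("CG", "CHG"):
                k = (part["motif_class"] == mclass).sum()
                rows.append(
                    {
                        "partition": f"class_within_{label}",
                        "label": mclass,
                        "fraction": k / len(part),
                        "n": int(k),
                    }
                )
    for mclass in ("CG", "CHG"):
        k = (sub["motif_class"] == mclass).sum()
        rows.append(
            {"partition": "class", "label": mclass, "fraction": k / total, "n": int(k)}
        )
    return pd.DataFrame(rows)


def write_gff3(
    path: str | Path,
    genes: dict[str, list[tuple[int, int]]],
    tes: dict[str, list[tuple[int, int]]],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Emit a minimal valid GFF3 with gene and TE (repeat) features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        gene_n = 0
        for contig in sorted(genes):
            for start, end in sorted(genes[contig]):
                gene_n += 1
                fh.write(
                    f"{contig}\tsynthetic\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                    f"ID=gene{gene_n:05d}\n"
                )
        te_n = 0
        for contig in sorted(tes):
            for start, end in sorted(tes[contig]):
                te_n += 1
                family = f"rnd-{(te_n % 5) + 1}_family-{te_n}"
                fh.write(
                    f"{contig}\tRepeatModeler\tdispersed_repeat\t{start + 1}\t{end}"
                    f"\t.\t+\t.\tID=te{te_n:05d};Name={family}\n"
                )


def naive_overlap(
    intervals: Iterable[tuple[int, int]], pos: int
) -> bool:
    """Reference O(n) point-overlap scan (used to validate tree lookups)."""
    return any(s <= pos < e for s, e in intervals)
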