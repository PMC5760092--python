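"""Genome annotation and operon-map containers.

Coordinates are 1-based inclusive throughout (GFF convention).  The
translation start site (TSS column here means the *translation* start,
i.e. the first base of the start codon) is the anchor for all
promoter-window arithmetic: it equals ``start`` on the plus strand and
``end`` on the minus strand.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import pandas as pd

GENE_COLUMNS = ["gene_id", "start", "end", "strand", "translation_start"]


def translation_start(start: int, end: int, strand: str) -> int:
    """First base of the start codon: ``start`` on '+', ``end`` on '-'."""
    return start if strand == "+" else end


@dataclass
class GenomeAnnotation:
    """ORF table for a (circular or linear) bacterial genome.

    Attributes
    ----------
    genes:
        DataFrame with columns ``gene_id, start, end, strand,
        translation_start``; one row per ORF, sorted by ``start``.
    genome_length:
        Total genome length in bp.
    """

    genes: pd.DataFrame
    genome_length: int

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"genes without a valid strand: {self.genes.loc[bad, 'gene_id'].tolist()}"
            )
        self.genes = self.genes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def translation_starts(self) -> pd.Series:
        return self.genes.set_index("gene_id")["translation_start"]

    def strands(self) -> pd.Series:
        return self.genes.set_index("gene_id")["strand"]

    def to_gff3(self, path: str, seqid: str = "chromosome") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {seqid} 1 {self.genome_length}\n")
            for row in self.genes.itertuples(index=False):
                attrs = f"ID={row.gene_id};locus_tag={row.gene_id}"
                fh.write(
                    f"{seqid}\tregulonscope\tgene\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str) -> "GenomeAnnotation":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        records = []
        for feat in db.features_of_type(("gene", "CDS")):
            gid = feat.attributes.get("ID", [feat.id])[0]
            records.append(
                dict(
                    gene_id=gid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    translation_start=translation_start(feat.start, feat.end, feat.strand),
                )
            )
        genome_length = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    genome_length = int(line.split()[-1])
        genes = pd.DataFrame(records, columns=GENE_COLUMNS).sort_values("start")
        if not genome_length:
            genome_length = int(genes["end"].max()) if len(genes) else 0
        return cls(genes=genes, genome_length=genome_length)


@dataclass
class OperonMap:
    """Operon membership: (operon_id, gene_id, rank) with rank 1 = leader.

    Ranks follow transcription order, so on the minus strand rank 1 is the
    rightmost gene.  A gene may belong to at most one operon.
    """

    members: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["operon_id", "gene_id", "rank"])
    )

    def __post_init__(self) -> None:
        dup = self.members["gene_id"].duplicated()
        if dup.any():
            genes = self.members.loc[dup, "gene_id"].tolist()
            raise ValueError(f"gene(s) listed in more than one operon: {genes}")
        self.members = self.members.reset_index(drop=True)

    def __len__(self) -> int:
        return self.members["operon_id"].nunique()

    def operon_of(self) -> pd.Series:
        return self.members.set_index("gene_id")["operon_id"]

    def ordered_members(self, operon_id) -> list:
        sub = self.members[self.members["operon_id"] == operon_id]
        return sub.sort_values("rank")["gene_id"].tolist()

    def iter_operons(self):
        for oid, sub in self.members.groupby("operon_id", sort=False):
            yield oid, sub.sort_values("rank")["gene_id"].tolist()

    def leaders(self) -> pd.Series:
        firsts = self.members[self.members["rank"] == 1]
        return firsts.set_index("operon_id")["gene_id"]

    def to_tsv(self, path: str) -> None:
        self.members.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "OperonMap":
        df = pd.read_csv(path, sep="\t")
        return cls(members=df[["operon_id", "gene_id", "rank"]])
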