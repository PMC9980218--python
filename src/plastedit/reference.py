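"""Plastome reference: sequence plus gene annotation.

The plastome is held as a single forward-strand sequence with a flat list of
gene features.  Genes are 1-based, inclusive intervals carrying a strand; an
inverted-repeat (IR) duplicate of a gene is a second feature whose sequence is
the reverse complement of the first copy.  All downstream coordinates (pileups,
editing sites, scan hits) live in this frame.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A gene feature on the plastome.

    ``name`` is unique among features; an IR duplicate carries the suffix
    ``_ir`` and records its template in ``copy_of``.  Coordinates are 1-based
    inclusive on the forward strand.
    """

    name: str
    start: int
    end: int
    strand: str  # "+" or "-"
    copy_of: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for gene {self.name}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval for gene {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class PlastomeReference:
    """Circular plastome sequence plus its gene annotation."""

    seq: str
    genes: list[Gene] = field(default_factory=list)
    name: str = "plastome"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        for g in self.genes:
            if g.end > len(self.seq):
                raise ValueError(f"gene {g.name} extends past the genome end")

    def __len__(self) -> int:
        return len(self.seq)

    def gene_at(self, position: int) -> Gene | None:
        """First gene containing a 1-based position, or None (intergenic)."""
        for g in self.genes:
            if g.contains(position):
                return g
        return None

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"no gene named {name!r}")

    def gene_sequence(self, name: str) -> str:
        """Coding-strand (5'->3') sequence of a gene."""
        g = self.gene(name)
        s = self.seq[g.start - 1 : g.end]
        return s if g.strand == "+" else revcomp(s)

    def coding_offset_to_position(self, gene: str, offset: int) -> int:
        """Map a 1-based offset along the coding strand to a forward-strand
        genome coordinate."""
        g = self.gene(gene)
        if not 1 <= offset <= g.length:
            raise ValueError(
                f"offset {offset} outside gene {gene} (length {g.length})"
            )
        return g.start + offset - 1 if g.strand == "+" else g.end - offset + 1

    def position_to_coding_offset(self, gene: str, position: int) -> int:
        g = self.gene(gene)
        if not g.contains(position):
            raise ValueError(f"position {position} outside gene {gene}")
        return position - g.start + 1 if g.strand == "+" else g.end - position + 1

    # ------------------------------------------------------------------ io

    def to_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.name, description="")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.name} 1 {len(self.seq)}\n")
            for g in self.genes:
                attrs = f"ID={g.name};Name={g.name}"
                if g.copy_of:
                    attrs += f";copy_of={g.copy_of}"
                fh.write(
                    f"{self.name}\tplastedit\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path) -> "PlastomeReference":
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single-sequence FASTA, got {len(records)}")
        rec = records[0]
        db = gffutils.create_db(
            str(gff3), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene", order_by="start"):
            copy_of = feat.attributes.get("copy_of", [None])[0]
            genes.append(
                Gene(feat.id, feat.start, feat.end, feat.strand, copy_of=copy_of)
            )
        return cls(seq=str(rec.seq), genes=genes, name=rec.id)


def read_exclusion_bed(path: str | Path) -> list[tuple[int, int]]:
    """Read a BED3 mask; returns 1-based inclusive intervals to exclude."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((int(start) + 1, int(end)))
    return intervals
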