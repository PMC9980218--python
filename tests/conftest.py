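from pathlib import Path

import pytest

from plastedit.reference import Gene, PlastomeReference, revcomp
from plastedit.simulate import SimConfig, plant_editing_sites, simulate_plastome


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(genome_length=20_000, n_genes=10, ir_gene=True,
                     mean_depth=100.0, error_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def plastome(sim_config) -> PlastomeReference:
    return simulate_plastome(sim_config)


def write_sam(path: Path, ref_name: str, length: int, records) -> Path:
    """Write a toy SAM file.

    Each record is (name, flag, pos_1based, mapq, cigar, seq).
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{ref_name}\tLN:{length}"]
    for name, flag, pos, mapq, cigar, seq in records:
        qual = "I" * len(seq)
        lines.append(
            f"{name}\t{flag}\t{ref_name}\t{pos}\t{mapq}\t{cigar}"
            f"\t*\t0\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def flip_reference(ref: PlastomeReference) -> PlastomeReference:
    """Reverse-complement a plastome: sequence flipped, gene intervals
    mirrored, strands inverted."""
    L = len(ref.seq)
    genes = [
        Gene(g.name, L - g.end + 1, L - g.start + 1,
             "-" if g.strand == "+" else "+", copy_of=g.copy_of)
        for g in ref.genes
    ]
    return PlastomeReference(seq=revcomp(ref.seq), genes=genes, name=ref.name)


def flip_sam(src: Path, dst: Path, length: int) -> Path:
    """Rewrite a SAM so every alignment refers to the reverse-complemented
    reference: positions mirrored, sequences complemented, strand bits
    flipped."""
    import pysam

    with pysam.AlignmentFile(str(src), "r", check_sq=False) as fin, \
            pysam.AlignmentFile(str(dst), "wh", header=fin.header) as fout:
        for read in fin:
            rl = read.query_length
            new = pysam.AlignedSegment(fout.header)
            new.query_name = read.query_name
            new.reference_id = read.reference_id
            new.reference_start = length - (read.reference_start + rl)
            new.cigartuples = read.cigartuples
            new.query_sequence = revcomp(read.query_sequence)
            new.query_qualities = read.query_qualities
            new.mapping_quality = read.mapping_quality
            new.flag = read.flag ^ 0x10 ^ (0x20 if read.is_paired else 0)
            fout.write(new)
    return dst
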