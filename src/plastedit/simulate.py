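"""Synthetic plastome, planted editing truth, simulated reads and Sanger traces.

The generator emulates a chloroplast RNA-seq experiment: an AT-rich circular
genome with genes on both strands and one gene duplicated in the inverted
repeat (IR, ndhB-like), C-to-U editing planted at chosen coding-strand
cytidines with per-condition fractions, 250-nt paired-end reads sampled
binomially edited/unedited at each site, and four-channel trace peak heights
standing in for Sanger bulk sequencing.  Reads are emitted pre-aligned (a
truth SAM), so no external aligner is needed; reads wholly inside an IR copy
additionally carry a MAPQ-0 secondary alignment at the mirrored copy, the way
a real aligner reports IR multi-mappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .reference import Gene, PlastomeReference, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# plastomes are AT-rich (~62% AT)
BASE_FREQS = np.array([0.31, 0.19, 0.19, 0.31])

GENE_NAME_POOL = [
    "ndhB", "rpoA", "rpoB", "rpoC2", "ndhD", "atpF", "psbE", "psbL",
    "rps2", "ndhG", "petB", "atpA", "ndhA", "rps14", "ndhF", "rpl20",
]


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults mirror the experimental design being emulated: a ~20 kb toy
    plastome (a real plastome is ~160 kb; scaled down for desk-scale runs),
    250-nt reads, and three biological replicates per condition (the silenced
    condition in the emulated design used four; the pipeline requests that
    explicitly where it matters).
    """

    genome_length: int = 20_000
    n_genes: int = 10
    ir_gene: bool = True
    read_length: int = 250
    mean_depth: float = 200.0
    error_rate: float = 0.001
    replicates_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_length >= self.genome_length:
            raise ValueError("read_length must be smaller than genome_length")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")


@dataclass(frozen=True)
class TruthSite:
    """A planted C-to-U editing site.

    ``position`` is the 1-based forward-strand genome coordinate; the
    coding-strand base there is C (forward C for + genes, forward G for -
    genes).  ``fractions`` maps condition labels to planted editing fractions.
    """

    gene: str
    position: int
    strand: str
    offset: int  # 1-based along the coding strand
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {cond} outside [0,1]: {f}")


def simulate_plastome(config: SimConfig) -> PlastomeReference:
    """Generate a random plastome with non-overlapping genes.

    Genes are placed left to right with random intergenic gaps and random
    strands.  With ``ir_gene`` the first gene (ndhB-like) is duplicated: a
    second feature ``<name>_ir`` whose region is the reverse complement of the
    first copy, on the opposite strand, so both copies encode the same
    transcript.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(BASES, size=config.genome_length, p=BASE_FREQS)

    names = list(GENE_NAME_POOL)
    while len(names) < config.n_genes:
        names.append(f"orf{len(names) + 1}")

    genes: list[Gene] = []
    cursor = int(rng.integers(100, 250)) if config.n_genes else 0
    for i in range(config.n_genes):
        length = int(rng.integers(600, 1400))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + 1  # 1-based
        end = start + length - 1
        genes.append(Gene(names[i], start, end, strand))
        cursor = end + int(rng.integers(100, 300))

    if config.ir_gene and config.n_genes >= 1:
        template = genes[0]
        length = template.length
        start = cursor + 1
        end = start + length - 1
        flipped = "-" if template.strand == "+" else "+"
        genes.append(Gene(f"{template.name}_ir", start, end, flipped,
                          copy_of=template.name))
        cursor = end

    if cursor > config.genome_length:
        raise ValueError(
            f"cannot pack {config.n_genes} genes into {config.genome_length} bp "
            f"(need {cursor})"
        )

    ref = PlastomeReference(seq=seq.tobytes().decode(), genes=genes,
                            name="synthetic_plastome")
    _sync_ir(ref)
    return ref


def _ir_pairs(ref: PlastomeReference) -> list[tuple[Gene, Gene]]:
    by_name = {g.name: g for g in ref.genes}
    return [(by_name[g.copy_of], g) for g in ref.genes if g.copy_of]


def _sync_ir(ref: PlastomeReference) -> None:
    """Rewrite each IR duplicate's region as the reverse complement of its
    template, keeping the two copies identical at the transcript level."""
    seq = list(ref.seq)
    for template, dup in _ir_pairs(ref):
        region = ref.seq[template.start - 1 : template.end]
        seq[dup.start - 1 : dup.end] = revcomp(region)
    ref.seq = "".join(seq)


def plant_editing_sites(
    ref: PlastomeReference,
    site_spec: list[tuple[str, int, dict[str, float]]],
    substitute: bool = True,
) -> list[TruthSite]:
    """Plant editing sites; returns the truth table and mutates ``ref``.

    Each spec entry is ``(gene, coding-strand offset, {condition: fraction})``.
    The coding-strand base at the offset must be C; with ``substitute`` the
    generator guarantees this by local substitution.  Sites planted in an IR
    template are mirrored into the duplicate (same transcript position, same
    fractions) and the duplicate's sequence is re-synchronised.
    """
    truth: list[TruthSite] = []
    seq = list(ref.seq)
    for gene_name, offset, fractions in site_spec:
        gene = ref.gene(gene_name)
        pos = ref.coding_offset_to_position(gene_name, offset)  # may raise
        fwd_base = seq[pos - 1]
        coding_base = fwd_base if gene.strand == "+" else revcomp(fwd_base)
        if coding_base != "C":
            if not substitute:
                raise ValueError(
                    f"coding-strand base at {gene_name}:{offset} is "
                    f"{coding_base}, not C"
                )
            seq[pos - 1] = "C" if gene.strand == "+" else "G"
        truth.append(TruthSite(gene_name, pos, gene.strand, offset,
                               dict(fractions)))
    ref.seq = "".join(seq)
    _sync_ir(ref)

    # mirror truth into IR duplicates of any gene that received sites
    for template, dup in _ir_pairs(ref):
        for site in [t for t in truth if t.gene == template.name]:
            pos = ref.coding_offset_to_position(dup.name, site.offset)
            truth.append(TruthSite(dup.name, pos, dup.strand, site.offset,
                                   dict(site.fractions)))
    truth.sort(key=lambda t: t.position)
    return truth


def truth_to_tsv(truth: list[TruthSite], path: str | Path) -> None:
    """Write the truth table in long format (one row per site x condition)."""
    ids = _truth_site_ids(truth)
    with open(path, "w") as fh:
        fh.write("site_id\tgene\tposition\tstrand\tcondition\tfraction\n")
        for site in truth:
            for cond in sorted(site.fractions):
                fh.write(
                    f"{ids[(site.gene, site.position)]}\t{site.gene}\t"
                    f"{site.position}\t{site.strand}\t{cond}\t"
                    f"{site.fractions[cond]:.6g}\n"
                )


def _truth_site_ids(truth: list[TruthSite]) -> dict[tuple[str, int], str]:
    """Site ids per the field's naming convention: within each gene, sites are
    numbered 1..k in 5'->3' transcript order; a single-site gene keeps the
    bare gene name."""
    ids: dict[tuple[str, int], str] = {}
    by_gene: dict[str, list[TruthSite]] = {}
    for t in truth:
        by_gene.setdefault(t.gene, []).append(t)
    for gene, sites in by_gene.items():
        sites.sort(key=lambda t: t.offset)
        for k, t in enumerate(sites, start=1):
            ids[(t.gene, t.position)] = gene if len(sites) == 1 else f"{gene}-{k}"
    return ids


# --------------------------------------------------------------------- reads


@dataclass
class SimulatedReads:
    fastq1: Path
    fastq2: Path
    sam: Path
    n_fragments: int


def simulate_reads(
    ref: PlastomeReference,
    truth: list[TruthSite],
    config: SimConfig,
    condition: str = "control",
    outdir: str | Path = ".",
    prefix: str = "reads",
    seed: int | None = None,
) -> SimulatedReads:
    """Simulate one library: paired FASTQ plus a truth SAM.

    Fragments are drawn uniformly (unstranded: either mate may be the
    forward read).  Each read overlapping a planted site carries the edited
    base with the site's planted fraction for ``condition``, independently per
    read; per-base substitution errors are added at ``config.error_rate``.
    Reads wholly inside an IR copy get a second, MAPQ-0 secondary alignment at
    the mirrored position of the other copy.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    L = len(ref.seq)
    read_len = config.read_length
    genome = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    genome_idx = np.zeros(L, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        genome_idx[genome == ord(b)] = i

    # per-site arrays (0-based position, edited forward-strand base index)
    site_pos = np.array([t.position - 1 for t in truth], dtype=np.int64)
    site_base = np.array(
        [BASE_INDEX["T"] if t.strand == "+" else BASE_INDEX["A"] for t in truth],
        dtype=np.int8,
    )
    site_frac = np.array(
        [t.fractions.get(condition, 0.0) for t in truth], dtype=float
    )

    ir_regions = [
        ((t.start - 1, t.end), (d.start - 1, d.end))
        for t, d in _ir_pairs(ref)
    ]

    n_frag = int(round(L * config.mean_depth / (2 * read_len)))
    frag_len = np.clip(
        np.round(rng.normal(450, 60, size=n_frag)).astype(int),
        max(300, read_len), min(600, L),
    )
    starts = rng.integers(0, L - frag_len + 1)  # 0-based
    frag_strand = rng.random(n_frag) < 0.5  # True: R1 forward

    qual = "I" * read_len
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": L}],
    }
    fq1_path = outdir / f"{prefix}_R1.fastq"
    fq2_path = outdir / f"{prefix}_R2.fastq"
    sam_path = outdir / f"{prefix}.sam"

    def make_read(a: int) -> np.ndarray:
        """Forward-strand base indices for a read aligned at 0-based a."""
        bases = genome_idx[a : a + read_len].copy()
        lo = np.searchsorted(site_pos, a)
        hi = np.searchsorted(site_pos, a + read_len)
        for k in range(lo, hi):
            if rng.random() < site_frac[k]:
                bases[site_pos[k] - a] = site_base[k]
        if config.error_rate > 0:
            err = rng.random(read_len) < config.error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                bases[err] = (bases[err] + shift) % 4
        return bases

    def to_str(bases: np.ndarray) -> str:
        return BASES[bases].tobytes().decode()

    def mirror(a: int, b: int) -> tuple[int, int] | None:
        """Mirrored 0-based half-open interval if [a,b) lies inside an IR copy."""
        for (t0, t1), (d0, d1) in ir_regions:
            if t0 <= a and b <= t1:
                return d0 + (t1 - b), d0 + (t1 - a)
            if d0 <= a and b <= d1:
                return t0 + (d1 - b), t0 + (d1 - a)
        return None

    with open(fq1_path, "w") as fq1, open(fq2_path, "w") as fq2, \
            pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for i in range(n_frag):
            s = int(starts[i])
            fl = int(frag_len[i])
            a1, a2 = s, s + fl - read_len  # 0-based starts of the two reads
            name = f"frag{i:07d}"
            r1_fwd = bool(frag_strand[i])
            bases_a = make_read(a1)
            bases_b = make_read(a2)
            # (ref_start, fwd_bases, is_reverse, is_read1)
            if r1_fwd:
                reads = [(a1, bases_a, False, True), (a2, bases_b, True, False)]
            else:
                reads = [(a2, bases_b, False, False), (a1, bases_a, True, True)]
            for pos, bases, is_rev, is_r1 in reads:
                seq_fwd = to_str(bases)
                read_seq = revcomp(seq_fwd) if is_rev else seq_fwd
                fq = fq1 if is_r1 else fq2
                fq.write(f"@{name}/{1 if is_r1 else 2}\n{read_seq}\n+\n{qual}\n")

                mirrored = mirror(pos, pos + read_len)
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = name
                rec.reference_id = 0
                rec.reference_start = pos
                rec.cigartuples = [(0, read_len)]
                rec.query_sequence = seq_fwd
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                rec.mapping_quality = 0 if mirrored else 60
                flag = 0x1 | 0x2 | (0x40 if is_r1 else 0x80)
                flag |= 0x10 if is_rev else 0x20
                rec.flag = flag
                sam.write(rec)
                if mirrored is not None:
                    m0, _ = mirrored
                    sec = pysam.AlignedSegment(sam.header)
                    sec.query_name = name
                    sec.reference_id = 0
                    sec.reference_start = m0
                    sec.cigartuples = [(0, read_len)]
                    sec.query_sequence = revcomp(seq_fwd)
                    sec.query_qualities = pysam.qualitystring_to_array(qual)
                    sec.mapping_quality = 0
                    sec.flag = (flag ^ 0x10 ^ 0x20) | 0x100
                    sam.write(sec)

    return SimulatedReads(fq1_path, fq2_path, sam_path, n_frag)


# --------------------------------------------------------------------- traces


@dataclass(frozen=True)
class ChannelPeaks:
    """Four-channel trace peak heights at one position (arbitrary units)."""

    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t) < 0:
            raise ValueError("peak heights must be non-negative")


def simulate_trace(
    fraction: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ChannelPeaks:
    """Trace peaks at an editing site sequenced on the coding strand.

    With no noise, height_T / (height_T + height_C) equals ``fraction``
    exactly.  ``noise_sd`` is the per-channel Gaussian noise as a fraction of
    the total C+T signal.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    total = 1000.0
    heights = np.array([0.0, (1.0 - fraction) * total, 0.0, fraction * total])
    if noise_sd > 0:
        heights = np.clip(heights + rng.normal(0, noise_sd * total, 4), 0, None)
    return ChannelPeaks(*heights)
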