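"""Editing-site calling and efficiency quantification.

Editing efficiency at a site is the fraction of reads carrying the edited
base out of reads carrying either state: T/(C+T) on the coding strand, which
on the forward reference strand is T/(C+T) for plus-strand genes and A/(G+A)
for minus-strand genes.  The pileup counts forward-strand bases per position
from a SAM alignment; multi-mapped records (MAPQ 0 or secondary) are counted
once per mapped location by default, so that sites inside the inverted repeat
remain observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

from .reference import PlastomeReference
from .simulate import ChannelPeaks

_BASE_ROWS = {"A": 0, "C": 1, "G": 2, "T": 3}


class UndefinedEfficiencyError(ValueError):
    """Raised when an efficiency is requested with zero informative reads;
    distinct from an efficiency of 0.0."""


class CallThresholds(NamedTuple):
    """Site-calling thresholds.

    The source analysis used a qualitative "low stringency" SNP filter; these
    numeric defaults are deliberately permissive and configurable.
    """

    min_depth: int = 10
    min_edited_reads: int = 2
    min_efficiency: float = 0.01
    include_multimapped: bool = True


class SiteCounts(NamedTuple):
    """Forward-strand base tallies at one 1-based position."""

    position: int
    a: int
    c: int
    g: int
    t: int
    other: int
    depth: int
    n_multimapped: int


@dataclass
class Pileup:
    """Per-position forward-strand base counts over the whole genome."""

    counts: np.ndarray        # (5, L): rows A, C, G, T, other
    multimapped: np.ndarray   # (L,) records with MAPQ 0 or secondary flag
    reference_name: str

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def at(self, position: int) -> SiteCounts:
        col = self.counts[:, position - 1]
        return SiteCounts(position, *map(int, col), int(col.sum()),
                          int(self.multimapped[position - 1]))

    def to_frame(self) -> pd.DataFrame:
        covered = np.nonzero(self.depth)[0]
        return pd.DataFrame({
            "position": covered + 1,
            "a": self.counts[0, covered],
            "c": self.counts[1, covered],
            "g": self.counts[2, covered],
            "t": self.counts[3, covered],
            "other": self.counts[4, covered],
            "depth": self.depth[covered],
            "n_multimapped": self.multimapped[covered],
        })


def _base_lut() -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)  # default: "other"
    for b, i in _BASE_ROWS.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut


_LUT = _base_lut()


def build_pileup(
    alignments: str | Path,
    ref: PlastomeReference,
    include_multimapped: bool = True,
) -> Pileup:
    """Count aligned bases per reference position from a SAM/BAM file.

    Unmapped records and soft-clipped bases are excluded.  Records with MAPQ 0
    or the secondary flag count as multi-mapped; with
    ``include_multimapped=False`` they are dropped entirely, otherwise each
    mapped location contributes once.
    """
    L = len(ref.seq)
    counts = np.zeros((5, L), dtype=np.int64)
    multi = np.zeros(L, dtype=np.int64)
    with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            if read.reference_name != ref.name:
                raise ValueError(
                    f"alignment reference {read.reference_name!r} does not "
                    f"match genome {ref.name!r}"
                )
            is_multi = read.mapping_quality == 0 or read.is_secondary
            if is_multi and not include_multimapped:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            qidx = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
            qpos, rpos = 0, read.reference_start
            for op, ln in read.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    if rpos + ln > L:
                        raise ValueError(
                            f"read {read.query_name} extends past the end of "
                            f"{ref.name}"
                        )
                    block = qidx[qpos : qpos + ln]
                    np.add.at(counts, (block, np.arange(rpos, rpos + ln)), 1)
                    if is_multi:
                        multi[rpos : rpos + ln] += 1
                    qpos += ln
                    rpos += ln
                elif op in (1, 4):   # I, S consume query only
                    qpos += ln
                elif op in (2, 3):   # D, N consume reference only
                    rpos += ln
    return Pileup(counts=counts, multimapped=multi, reference_name=ref.name)


def editing_efficiency(edited: int, unedited: int) -> float:
    """Edited fraction edited/(edited+unedited); the undefined 0/0 case raises
    UndefinedEfficiencyError rather than returning 0.0."""
    if edited < 0 or unedited < 0:
        raise ValueError("counts must be non-negative")
    total = edited + unedited
    if total == 0:
        raise UndefinedEfficiencyError("no informative reads at site")
    return edited / total


def format_percent(efficiency: float) -> str:
    """Render an efficiency as percent with two decimals (0.0543 -> '5.43%')."""
    return f"{efficiency * 100:.2f}%"


def call_editing_sites(
    pileup: Pileup,
    ref: PlastomeReference,
    thresholds: CallThresholds = CallThresholds(),
    exclude: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Call C-to-U editing sites strand-aware from a pileup.

    A site is called at position p iff the coding-strand reference base is C
    (forward C in + genes, forward G in - genes), total depth >= min_depth,
    edited reads >= min_edited_reads and efficiency >= min_efficiency.
    Efficiency uses coding-strand C/T (equivalently G/A) counts only.
    Positions outside any gene are scanned in both orientations and reported
    with gene="intergenic".  ``exclude`` is a list of 1-based inclusive
    intervals to mask (e.g. known SNPs).
    """
    L = len(ref.seq)
    refarr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    depth = pileup.depth
    masked = np.zeros(L, dtype=bool)
    for s, e in exclude or []:
        masked[s - 1 : e] = True

    in_gene = np.zeros(L, dtype=bool)
    rows: list[dict] = []

    def scan(lo: int, hi: int, strand: str, gene_name: str) -> None:
        """Scan 0-based [lo, hi) for sites on the given coding strand."""
        idx = np.arange(lo, hi)
        if strand == "+":
            cand = idx[(refarr[idx] == ord("C")) & ~masked[idx]]
            edited_row, unedited_row = _BASE_ROWS["T"], _BASE_ROWS["C"]
        else:
            cand = idx[(refarr[idx] == ord("G")) & ~masked[idx]]
            edited_row, unedited_row = _BASE_ROWS["A"], _BASE_ROWS["G"]
        if cand.size == 0:
            return
        ed = pileup.counts[edited_row, cand]
        un = pileup.counts[unedited_row, cand]
        dp = depth[cand]
        denom = ed + un
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = np.where(denom > 0, ed / np.maximum(denom, 1), np.nan)
        keep = (
            (dp >= thresholds.min_depth)
            & (ed >= thresholds.min_edited_reads)
            & (denom > 0)
            & (eff >= thresholds.min_efficiency)
        )
        for p, e_cnt, u_cnt, d, f in zip(
            cand[keep], ed[keep], un[keep], dp[keep], eff[keep]
        ):
            rows.append({
                "gene": gene_name,
                "position": int(p) + 1,
                "strand": strand,
                "edited_count": int(e_cnt),
                "unedited_count": int(u_cnt),
                "efficiency": float(f),
                "depth": int(d),
                "n_multimapped": int(pileup.multimapped[p]),
            })

    for g in ref.genes:
        in_gene[g.start - 1 : g.end] = True
    for g in ref.genes:
        scan(g.start - 1, g.end, g.strand, g.name)
    # intergenic: forward C (as +) and forward G (as -) both considered
    inter = np.nonzero(~in_gene)[0]
    if inter.size:
        # contiguous runs keep scan() interval-based
        breaks = np.nonzero(np.diff(inter) > 1)[0]
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [inter.size - 1]))
        for rs, re_ in zip(run_starts, run_ends):
            lo, hi = int(inter[rs]), int(inter[re_]) + 1
            scan(lo, hi, "+", "intergenic")
            scan(lo, hi, "-", "intergenic")

    df = pd.DataFrame(
        rows,
        columns=["gene", "position", "strand", "edited_count",
                 "unedited_count", "efficiency", "depth", "n_multimapped"],
    )
    return df.sort_values("position", kind="stable").reset_index(drop=True)


def name_sites(sites: pd.DataFrame, ref: PlastomeReference) -> pd.DataFrame:
    """Assign site ids: within each gene, sites numbered 1..k in 5'->3'
    transcript order (descending genome coordinate for minus-strand genes);
    a gene with a single site keeps the bare gene name.  Intergenic sites are
    named by position."""
    df = sites.copy()
    ids = pd.Series(index=df.index, dtype=object)
    for gene, group in df.groupby("gene", sort=False):
        if gene == "intergenic":
            ids.loc[group.index] = [
                f"intergenic-{p}" for p in group["position"]
            ]
            continue
        ascending = ref.gene(gene).strand == "+"
        ordered = group.sort_values("position", ascending=ascending)
        if len(ordered) == 1:
            ids.loc[ordered.index] = gene
        else:
            ids.loc[ordered.index] = [
                f"{gene}-{k}" for k in range(1, len(ordered) + 1)
            ]
    df.insert(0, "site_id", ids)
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site ids: {dups}")
    return df


def harmonize_site_ids(long_table: pd.DataFrame,
                       ref: PlastomeReference,
                       min_replicates: int = 2) -> pd.DataFrame:
    """Re-assign site ids from the pooled position set of a multi-replicate
    table.

    Per-replicate naming is unstable when a noise call lands inside a gene
    that also carries real sites (the within-gene numbering shifts in that
    replicate only).  Positions observed in at least ``min_replicates``
    libraries form the site catalogue and are named once, in transcript
    order, over their union; one-off calls get a provisional positional id
    ("<gene>@<position>") so they cannot perturb the catalogue numbering.
    """
    counts = long_table.groupby(["gene", "position"]).size()
    reproducible = counts[counts >= min_replicates].index
    unique = (long_table[["gene", "position", "strand"]]
              .drop_duplicates().reset_index(drop=True))
    keep = unique.set_index(["gene", "position"]).index.isin(reproducible)
    named = name_sites(unique[keep].reset_index(drop=True), ref)
    mapping = dict(zip(zip(named["gene"], named["position"]),
                       named["site_id"]))
    out = long_table.copy()
    out["site_id"] = [
        mapping.get((g, p), f"{g}@{p}")
        for g, p in zip(out["gene"], out["position"])
    ]
    return out


def sanger_efficiency(peaks: ChannelPeaks, strand: str = "+") -> float:
    """Editing efficiency from trace peak heights: T/(C+T) on the coding
    strand; for a trace read off the antisense strand the complementary
    channels A/(G+A) are used."""
    if strand == "+":
        ed, un = peaks.t, peaks.c
    elif strand == "-":
        ed, un = peaks.a, peaks.g
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if ed + un <= 0:
        raise UndefinedEfficiencyError("both informative channels are zero")
    return ed / (ed + un)
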