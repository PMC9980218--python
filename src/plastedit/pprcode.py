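"""PPR-code target prediction: PWM construction and exact-p-value scanning.

A PLS-class PPR protein recognises roughly one nucleotide per repeat motif,
with specificity determined by the residues at motif position 6 and position
1' (the first residue of the next motif).  A code table maps (aa6, aa1')
pairs to nucleotide preference vectors; stacking one column per motif in
N-to-C order (the N-terminal motif pairing with the 5' base) gives a PWM.
Scanning converts columns to log-odds against a 0-order background and
assigns every window an exact p-value: the tail probability of its score
under the background, computed by dynamic programming over the discretized
score distribution (the same construction FIMO uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import PlastomeReference, revcomp

NUCS = "ACGU"
_DNA_ORDER = "ACGT"
PLS_CLASSES = {"P", "L", "S", "P1", "L1", "S1", "P2", "L2", "S2"}
TERMINAL_CLASSES = {"E", "E+", "E1", "E2", "DYW"}

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PPRMotif:
    """One PLS repeat: order from the N-terminus, motif class, and the two
    code residues (aa at position 6, aa at 1' of the following motif; '-' if
    absent)."""

    index: int
    motif_class: str
    aa6: str
    aa1p: str

    def __post_init__(self) -> None:
        for aa in (self.aa6, self.aa1p):
            if aa != "-" and aa.upper() not in _AA:
                raise ValueError(f"invalid residue {aa!r} in motif {self.index}")


class CodeTable:
    """Mapping (aa6, aa1') -> probability vector over A, C, G, U.

    Pairs absent from the table fall back to a uniform column (no
    preference), as do motifs with a gap residue.
    """

    def __init__(self, mapping: dict[tuple[str, str], np.ndarray],
                 fallback: np.ndarray | None = None):
        self.mapping = {}
        for pair, vec in mapping.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (4,) or (vec < 0).any() or abs(vec.sum() - 1) > 1e-9:
                raise ValueError(
                    f"code row for {pair} is not a probability vector"
                )
            self.mapping[(pair[0].upper(), pair[1].upper())] = vec
        self.fallback = (np.full(4, 0.25) if fallback is None
                         else np.asarray(fallback, dtype=float))
        if abs(self.fallback.sum() - 1) > 1e-9:
            raise ValueError("fallback is not a probability vector")

    def lookup(self, aa6: str, aa1p: str) -> np.ndarray:
        if aa6 == "-" or aa1p == "-":
            return self.fallback
        return self.mapping.get((aa6.upper(), aa1p.upper()), self.fallback)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodeTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = ["aa6", "aa1p", "pA", "pC", "pG", "pU"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"code table missing columns {missing}")
        mapping = {
            (str(r.aa6), str(r.aa1p)): np.array([r.pA, r.pC, r.pG, r.pU])
            for r in df.itertuples()
        }
        return cls(mapping)


def default_code_table() -> CodeTable:
    """The code table shipped with the package (data/ppr_code_synthetic.tsv)."""
    return CodeTable.from_tsv(_data_path("ppr_code_synthetic.tsv"))


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def parse_motifs(table: str | Path | pd.DataFrame) -> list[PPRMotif]:
    """Read an ordered PLS motif table (columns: index, class, aa6, aa1p).

    C-terminal E/E+/DYW rows, which do not contribute PWM columns, are
    dropped; the remaining PLS motifs must have contiguous indices.
    """
    df = (table if isinstance(table, pd.DataFrame)
          else pd.read_csv(table, sep="\t", comment="#"))
    required = ["index", "class", "aa6", "aa1p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"motif table missing columns {missing}")
    df = df.sort_values("index")
    pls = df[df["class"].isin(PLS_CLASSES)]
    if pls.empty:
        raise ValueError("no PLS motifs in table: nothing to scan with")
    idx = pls["index"].to_numpy()
    if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
        raise ValueError("motif indices are not contiguous")
    return [
        PPRMotif(int(row["index"]), str(row["class"]),
                 str(row["aa6"]), str(row["aa1p"]))
        for _, row in pls.iterrows()
    ]


@dataclass
class PWM:
    """Motif-derived position weight matrix with discretized log-odds.

    ``probs`` holds one probability column per PLS motif (shape L x 4 over
    A,C,G,U in N->C order, the N-terminal motif reading the 5' base);
    ``log_odds`` is log2(p/background) after a pseudocount.  ``int_scores``
    are the log-odds shifted per column to a zero minimum and rounded to
    multiples of ``granularity``, the representation the exact null
    distribution is computed over.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float
    log_odds: np.ndarray = field(init=False)
    granularity: float = field(init=False)
    int_scores: np.ndarray = field(init=False)
    offset: float = field(init=False)
    bins: int = 1000

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be an L x 4 matrix")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-9 or (bg <= 0).any():
            raise ValueError("background must be a positive probability vector")
        padded = (p + self.pseudocount) / (1 + 4 * self.pseudocount)
        self.log_odds = np.log2(padded / bg)
        col_min = self.log_odds.min(axis=1, keepdims=True)
        self.offset = float(col_min.sum())
        score_range = float((self.log_odds.max(axis=1) - col_min[:, 0]).sum())
        if score_range == 0.0:
            self.granularity = 1.0
            self.int_scores = np.zeros_like(self.log_odds, dtype=np.int64)
        else:
            self.granularity = score_range / self.bins
            self.int_scores = np.round(
                (self.log_odds - col_min) / self.granularity
            ).astype(np.int64)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Most-preferred base per column, as DNA."""
        return "".join(_DNA_ORDER[i] for i in self.probs.argmax(axis=1))


def build_pwm(
    motifs: list[PPRMotif],
    code: CodeTable | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
    bins: int = 1000,
) -> PWM:
    """One PWM column per PLS motif, N->C order, via the code table.

    Unlisted (aa6, aa1') pairs and gap residues get the table's fallback
    (uniform) column.  ``background`` defaults to uniform; pass the scanned
    genome's 0-order frequencies for FIMO-like behaviour on AT-rich plastomes.
    """
    if not motifs:
        raise ValueError("empty motif list")
    if code is None:
        code = default_code_table()
    probs = np.stack([code.lookup(m.aa6, m.aa1p) for m in motifs])
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount, bins=bins)


def estimate_background(seq: str) -> np.ndarray:
    """0-order nucleotide frequencies of a DNA sequence (T read as U)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    counts = np.array([(arr == ord(b)).sum() for b in _DNA_ORDER], dtype=float)
    if counts.sum() == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return counts / counts.sum()


@dataclass
class NullDistribution:
    """Exact pmf of the total discretized score of a background window."""

    pmf: np.ndarray   # index = integer score
    sf: np.ndarray    # sf[s] = P(score >= s)
    granularity: float
    offset: float

    def p_value(self, int_score: int) -> float:
        if int_score < 0:
            return 1.0
        if int_score >= len(self.sf):
            return float(self.sf[-1])
        return float(self.sf[int_score])


def exact_null(pwm: PWM) -> NullDistribution:
    """Null score distribution by column-wise convolution.

    For a random sequence of PWM length drawn from the background, the pmf of
    the total integer score is the convolution over columns of the
    four-outcome per-column distributions; p-values are its tail sums.
    """
    if pwm.granularity <= 0:
        raise ValueError("granularity must be positive")
    pmf = np.array([1.0])
    for c in range(len(pwm)):
        col_scores = pwm.int_scores[c]
        width = int(col_scores.max()) + 1
        col_pmf = np.zeros(width)
        np.add.at(col_pmf, col_scores, pwm.background)
        pmf = np.convolve(pmf, col_pmf)
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"null pmf sums to {total}, not 1")
    sf = np.cumsum(pmf[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    return NullDistribution(pmf=pmf, sf=sf, granularity=pwm.granularity,
                            offset=pwm.offset)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_DNA_ORDER):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    lut[ord("U")] = 3
    lut[ord("u")] = 3
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(integer scores, real log-odds scores) for every window of one strand.

    Ambiguous bases take the background-weighted column average score.
    """
    enc = _encode(seq)
    L = len(pwm)
    # 5th column: expected score for an ambiguous base
    int_ext = np.concatenate(
        [pwm.int_scores,
         np.round(pwm.int_scores @ pwm.background)[:, None]], axis=1
    ).astype(np.int64)
    real_ext = np.concatenate(
        [pwm.log_odds, (pwm.log_odds @ pwm.background)[:, None]], axis=1
    )
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    cols = np.arange(L)
    ints = int_ext[cols, windows].sum(axis=1)
    reals = real_ext[cols, windows].sum(axis=1)
    return ints, reals


def scan_genome(
    pwm: PWM,
    genome: str | PlastomeReference,
    strands: str = "both",
) -> pd.DataFrame:
    """Score every window on the requested strands with exact p-values.

    Returns a table with 1-based forward coordinates; minus-strand hits are
    reported in forward coordinates with strand '-'.  ``score`` is the
    log-odds sum; ``p_value`` the exact tail probability from the null.
    """
    seq = genome.seq if isinstance(genome, PlastomeReference) else genome
    seq = seq.upper()
    L = len(pwm)
    if len(seq) < L:
        raise ValueError("genome shorter than the PWM")
    if strands not in ("both", "+", "-"):
        raise ValueError(f"invalid strands {strands!r}")
    null = exact_null(pwm)
    n = len(seq) - L + 1

    frames = []
    if strands in ("both", "+"):
        ints, reals = _window_scores(pwm, seq)
        frames.append(pd.DataFrame({
            "start": np.arange(1, n + 1),
            "strand": "+",
            "score": reals,
            "p_value": null.sf[np.clip(ints, 0, len(null.sf) - 1)],
        }))
    if strands in ("both", "-"):
        rc = revcomp(seq)
        ints, reals = _window_scores(pwm, rc)
        # window at rc position i (0-based) covers forward [len-i-L, len-i)
        starts = len(seq) - np.arange(n) - L + 1
        frames.append(pd.DataFrame({
            "start": starts,
            "strand": "-",
            "score": reals,
            "p_value": null.sf[np.clip(ints, 0, len(null.sf) - 1)],
        }))
    hits = pd.concat(frames, ignore_index=True)
    hits["end"] = hits["start"] + L - 1
    hits["sequence"] = [
        seq[s - 1 : s + L - 1] if st == "+" else revcomp(seq[s - 1 : s + L - 1])
        for s, st in zip(hits["start"], hits["strand"])
    ]
    return hits[["start", "end", "strand", "sequence", "score", "p_value"]]


def rank_hits(hits: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k hits by ascending p-value; ties broken by descending score, then
    ascending coordinate (plus strand first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = hits.sort_values(
        by=["p_value", "score", "start", "strand"],
        ascending=[True, False, True, True],
        kind="stable",
    ).head(k).reset_index(drop=True)
    ordered.insert(0, "rank", np.arange(1, len(ordered) + 1))
    return ordered
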