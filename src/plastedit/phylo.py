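"""Ortholog phylogeny: p-distances, neighbor joining, bootstrap support.

Distances are uncorrected p-distances (proportion of differing residues per
aligned site, pairwise gap deletion by default).  Trees are built with the
Saitou-Nei neighbor-joining agglomeration and returned unrooted as dendropy
trees; bootstrap support for each internal bipartition of the full-data tree
is the fraction of column-resampled replicates containing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import AlignIO

GAP_CHARS = frozenset("-.")


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into (id, row) pairs."""
    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def _to_matrix(aln) -> tuple[list[str], np.ndarray]:
    """Alignment -> (labels, n x m byte matrix). Accepts (id, seq) pairs or
    Biopython alignment/SeqRecord iterables."""
    pairs = []
    for item in aln:
        if isinstance(item, tuple):
            pairs.append((item[0], item[1]))
        else:  # SeqRecord
            pairs.append((item.id, str(item.seq)))
    if len(pairs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    labels = [p[0] for p in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids in alignment")
    mat = np.array([list(s.upper().encode()) for _, s in pairs], dtype=np.uint8)
    return labels, mat


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with taxon labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix has a non-zero diagonal")
        if (v < 0).any():
            raise ValueError("negative distances")
        self.values = v


def p_distance(aln, gap_mode: str = "pairwise") -> DistanceMatrix:
    """Pairwise proportion of differing sites.

    ``gap_mode``: "pairwise" (default) drops, per pair, columns gapped in
    either member; "complete" drops columns gapped in any row before
    comparing.  A pair with no comparable columns is an error naming the
    pair.
    """
    labels, mat = _to_matrix(aln)
    if gap_mode not in ("pairwise", "complete"):
        raise ValueError(f"invalid gap_mode {gap_mode!r}")
    is_gap = np.isin(mat, [ord(c) for c in GAP_CHARS])
    if gap_mode == "complete":
        keep = ~is_gap.any(axis=0)
        mat = mat[:, keep]
        is_gap = is_gap[:, keep]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~is_gap[i] & ~is_gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            d[i, j] = d[j, i] = (mat[i, ok] != mat[j, ok]).sum() / m
    return DistanceMatrix(labels=labels, values=d)


def neighbor_joining(
    dm: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined, with the standard branch-length and distance-update formulas; the
    last three nodes are joined by the three-point formulas.  Negative branch
    lengths are clamped to zero (with a warning).  Ties in Q break by lowest
    index, so taxon order fixes the output.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        taxon = tns.get_taxon(lab)
        if taxon is None:
            raise ValueError(f"taxon {lab!r} missing from namespace")
        nodes.append(dendropy.Node(taxon=taxon))

    clamped = False

    def edge_len(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return float(x)

    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.values
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        ix = np.ix_(active, active)
        sub = D[ix]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = edge_len(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = edge_len(lj)
        for k in active:
            if k in (i, j):
                continue
            D[nxt, k] = D[k, nxt] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for k, lk in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = edge_len(lk)

    if clamped:
        warnings.warn("negative NJ branch lengths clamped to zero",
                      stacklevel=2)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _internal_bitmasks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    masks = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.head_node.is_leaf():
            continue
        masks.add(edge.bipartition.split_bitmask)
    return masks


def bootstrap_support(
    aln,
    n_reps: int = 1000,
    seed: int | None = None,
    gap_mode: str = "pairwise",
) -> dendropy.Tree:
    """NJ tree from the full alignment, internal nodes labelled with bootstrap
    support: the fraction of ``n_reps`` column-resampled replicates whose NJ
    tree contains the same bipartition.  Deterministic under ``seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, mat = _to_matrix(aln)
    rng = np.random.default_rng(seed)
    pairs = [(lab, mat[i].tobytes().decode()) for i, lab in enumerate(labels)]
    full_tree = neighbor_joining(p_distance(pairs, gap_mode=gap_mode))
    tns = full_tree.taxon_namespace
    full_tree.encode_bipartitions()

    target_edges = [
        e for e in full_tree.preorder_edge_iter()
        if e.head_node is not full_tree.seed_node
        and not e.head_node.is_leaf()
    ]
    counts = {e.bipartition.split_bitmask: 0 for e in target_edges}

    m = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        resampled = [
            (lab, mat[i, cols].tobytes().decode())
            for i, lab in enumerate(labels)
        ]
        with warnings.catch_warnings():
            # replicate trees routinely need clamping; not worth a warning each
            warnings.simplefilter("ignore", UserWarning)
            rep_tree = neighbor_joining(
                p_distance(resampled, gap_mode=gap_mode), taxon_namespace=tns
            )
        for mask in _internal_bitmasks(rep_tree):
            if mask in counts:
                counts[mask] += 1

    for e in target_edges:
        support = counts[e.bipartition.split_bitmask] / n_reps
        e.head_node.label = f"{support:.3f}"
    return full_tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))
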