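"""Consensus proteins and neighbor-joining phylogenetics.

For each genotype the most prevalent protein clusters are summarised into a
consensus sequence via a center-star multiple alignment (deterministic and
adequate for near-identical amplicon proteins).  Consensus proteins across
genotypes are then aligned the same way; pairwise p-distances (proportion
of differing sites, pairwise deletion of gap/X sites) feed the
Saitou-Nei neighbor-joining algorithm, with branch support from bootstrap
resampling of alignment columns.
"""

from __future__ import annotations

import io as _io
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from skbio import TreeNode

from .cluster import ProteinCluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows over amino acids + '-'."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows) or not self.rows:
            raise ValueError("names/rows mismatch or empty alignment")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate names in alignment")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows of unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class DistanceMatrix:
    names: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.names), len(self.names)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("asymmetric distance matrix")
        if (d < 0).any():
            raise ValueError("negative distance")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("non-zero diagonal")
        object.__setattr__(self, "d", d)


def top_clusters(
    selected_clusters: Sequence[ProteinCluster], k: int = 10
) -> list[ProteinCluster]:
    """The k largest clusters (ties by lexicographic representative)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not selected_clusters:
        raise ValueError("empty cluster set")
    ordered = sorted(selected_clusters, key=lambda c: (-c.size, c.representative))
    if len(ordered) < k:
        logger.warning(
            "only %d clusters available for top-%d selection", len(ordered), k
        )
    return ordered[:k]


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _split_by_center(c_gapped: str, s_gapped: str, n: int) -> tuple[list[str], list[str]]:
    """Decompose a pairwise alignment into, per center residue, the chars of s
    inserted before it (where the center row has gaps) and the char matched to
    it; index n holds the trailing insert."""
    inserts = [""] * (n + 1)
    matched = [""] * n
    j = 0
    for cc, sc in zip(c_gapped, s_gapped):
        if cc == "-":
            inserts[j] += sc
        else:
            matched[j] = sc
            j += 1
    return inserts, matched


def align_center_star(
    seqs: Sequence[str],
    names: Sequence[str] | None = None,
    match: float = 1,
    mismatch: float = -1,
    gap: float = -2,
) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence maximising the summed pairwise global
    alignment score against all others (ties to the smallest index); every
    other sequence is aligned to the center pairwise with linear gap
    penalties, and the pairwise alignments are merged gap-compatibly
    ("once a gap, always a gap").
    """
    if not seqs:
        raise ValueError("no sequences")
    if names is None:
        names = tuple(f"seq{i}" for i in range(len(seqs)))
    names = tuple(names)
    if len(names) != len(seqs):
        raise ValueError("names/seqs length mismatch")
    if len(seqs) == 1:
        return Alignment(names=names, rows=(seqs[0],))

    aligner = _make_aligner(match, mismatch, gap)
    k = len(seqs)
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = aligner.score(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))  # argmax takes first on ties
    c_seq = seqs[center]
    n = len(c_seq)

    others = [i for i in range(k) if i != center]
    profiles: dict[int, tuple[list[str], list[str]]] = {}
    for i in others:
        aln = aligner.align(c_seq, seqs[i])[0]
        profiles[i] = _split_by_center(str(aln[0]), str(aln[1]), n)

    gap_runs = [0] * (n + 1)
    for inserts, _ in profiles.values():
        for pos in range(n + 1):
            gap_runs[pos] = max(gap_runs[pos], len(inserts[pos]))

    def lift(inserts: list[str], matched: list[str]) -> str:
        parts = []
        for pos in range(n):
            parts.append(inserts[pos].ljust(gap_runs[pos], "-"))
            parts.append(matched[pos])
        parts.append(inserts[n].ljust(gap_runs[n], "-"))
        return "".join(parts)

    center_row = lift([""] * (n + 1), list(c_seq))
    rows: list[str] = [""] * k
    rows[center] = center_row
    for i in others:
        rows[i] = lift(*profiles[i])
    return Alignment(names=names, rows=tuple(rows))


def consensus(alignment: Alignment, min_plurality: float = 0.5) -> str:
    """Plurality consensus of an alignment.

    Columns that are gaps in more than half the rows are dropped.  Otherwise
    the most frequent non-gap residue wins if its frequency among non-gap
    rows is at least ``min_plurality`` (ties to the lexicographically
    smallest residue); below-plurality columns become 'X'.
    """
    out = []
    n_rows = len(alignment.rows)
    for col in zip(*alignment.rows):
        gaps = col.count("-")
        if gaps * 2 > n_rows:
            continue
        residues = Counter(c for c in col if c != "-")
        best = min(residues.items(), key=lambda kv: (-kv[1], kv[0]))
        if best[1] / (n_rows - gaps) >= min_plurality:
            out.append(best[0])
        else:
            out.append("X")
    return "".join(out)


_EXCLUDED = frozenset("-X")


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Sites where either row holds a gap or 'X' are excluded; having no
    comparable sites at all is an error.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows of unequal length")
    compared = 0
    mismatches = 0
    for a, b in zip(row_a, row_b):
        if a in _EXCLUDED or b in _EXCLUDED:
            continue
        compared += 1
        mismatches += a != b
    if compared == 0:
        raise ValueError("no comparable sites between rows")
    return mismatches / compared


def p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    k = len(alignment.rows)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d[i, j] = d[j, i] = p_distance(alignment.rows[i], alignment.rows[j])
            except ValueError as exc:
                raise ValueError(
                    f"no comparable sites between {alignment.names[i]!r} and "
                    f"{alignment.names[j]!r}"
                ) from exc
    return DistanceMatrix(names=alignment.names, d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimising the Q-criterion (ties to the
    smallest index pair); branch lengths from the standard formulas, with
    negative lengths clamped to zero and the deficit moved to the sister
    edge.  Two taxa yield a single edge of the full distance, written as a
    root with two half-length children.
    """
    n = len(dm.names)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.names]
    D = dm.d.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair among minima
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        i, j = divmod(int(flat), m)
        for a in range(m):
            done = False
            for b in range(a + 1, m):
                if Q[a, b] == qmin:
                    i, j = a, b
                    done = True
                    break
            if done:
                break
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        elif lj < 0:
            li, lj = D[i, j], 0.0
        left, right = nodes[i], nodes[j]
        left.length = float(li)
        right.length = float(lj)
        parent = TreeNode(children=[left, right])
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [a for a in range(m) if a not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        nodes = [nodes[a] for a in keep] + [parent]

    a, b = nodes
    d_ab = float(D[0, 1])
    a.length = d_ab / 2
    b.length = d_ab / 2
    return TreeNode(children=[a, b])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, canonicalised to the side not
    containing the lexicographically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    total = set(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(total) - len(side) < 2:
            continue
        if anchor in side:
            side = total - side
        out.add(frozenset(side))
    return out


def bootstrap_support(
    alignment: Alignment, n_reps: int = 1000, seed: int = 0
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Bootstrap branch support for the NJ tree of an alignment.

    Columns are resampled with replacement ``n_reps`` times from a single
    seeded stream (replicate r consumes draw r, so supports depend only on
    the seed and n_reps).  Support is the percentage of replicates whose NJ
    tree contains the same leaf bipartition.  Replicates in which some pair
    has no comparable sites contribute no support.  The returned tree is the
    full-alignment NJ tree with internal nodes labelled by integer support.
    """
    if alignment.n_columns < 1:
        raise ValueError("empty alignment")
    tree = neighbor_joining(p_distance_matrix(alignment))
    base_parts = bipartitions(tree)
    counts: Counter = Counter()
    rng = np.random.default_rng(seed)

    mat = np.array([list(row) for row in alignment.rows])
    valid = ~np.isin(mat, ("-", "X"))
    k, ncol = mat.shape
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        M = mat[:, idx]
        V = valid[:, idx]
        d = np.zeros((k, k))
        ok = True
        for i in range(k):
            for j in range(i + 1, k):
                both = V[i] & V[j]
                total = int(both.sum())
                if total == 0:
                    ok = False
                    break
                d[i, j] = d[j, i] = int(((M[i] != M[j]) & both).sum()) / total
            if not ok:
                break
        if not ok:
            continue
        rep_tree = neighbor_joining(DistanceMatrix(alignment.names, d))
        for part in bipartitions(rep_tree):
            counts[part] += 1

    supports = {
        part: 100.0 * counts.get(part, 0) / n_reps for part in base_parts
    }
    anchor = sorted(alignment.names)[0]
    total = set(alignment.names)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(total) - len(side) < 2:
            continue
        canon = frozenset(total - side if anchor in side else side)
        node.name = str(int(round(supports[canon])))
    return tree, supports


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string (branch lengths; internal node
    labels carry bootstrap supports where annotated)."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def genotype_consensi(
    selected_clusters: dict[str, Sequence[ProteinCluster]],
    k: int = 10,
    min_plurality: float = 0.5,
) -> list[tuple[str, str]]:
    """Per-genotype consensus protein from the k most prevalent clusters."""
    out = []
    for genotype in sorted(selected_clusters):
        clusters = selected_clusters[genotype]
        if not clusters:
            logger.warning("genotype %s has no selected clusters; skipped", genotype)
            continue
        top = top_clusters(clusters, k=k)
        aln = align_center_star([c.representative for c in top])
        out.append((genotype, consensus(aln, min_plurality=min_plurality)))
    return out
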