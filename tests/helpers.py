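"""Independent brute-force oracles and small utilities shared by the tests.

Everything here is deliberately written as the most literal possible
computation (position scans, exhaustive overlap search, recursive alignment
scoring) so it stays independent of the library code paths it checks.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache

import numpy as np

from gliascan.cluster import ProteinRecord, cluster_identical, filter_stops, translate_cds
from gliascan.preprocess import (
    ReadPair,
    demultiplex,
    merge_pair,
    quality_trim,
    strip_technical,
)

RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(RC)[::-1]


def brute_quality_trim(seq, qual, window_size=4, mean_q=20, min_len=36):
    cut = len(seq)
    for i in range(len(seq) - window_size + 1):
        if sum(qual[i : i + window_size]) / window_size < mean_q:
            cut = i
            break
    if cut < min_len:
        return None
    return seq[:cut], qual[:cut]


def brute_merge(pair: ReadPair, min_overlap=10, max_mismatch_density=0.25):
    """Literal exhaustive overlap search mirroring the merge contract."""
    fwd = pair.fwd_seq
    rev = revcomp(pair.rev_seq)
    lf, lr = len(fwd), len(rev)
    best = None  # (score, L)
    for L in range(min(lf, lr), min_overlap - 1, -1):
        mism = sum(
            1
            for a, b in zip(fwd[lf - L :], rev[:L])
            if a != b or a == "N" or b == "N"
        )
        if mism / L > max_mismatch_density:
            continue
        score = (L - mism) - mism
        if best is None or score > best[0] or (score == best[0] and L > best[1]):
            best = (score, L)
    if best is None:
        return None
    return best[1]  # chosen overlap length


def brute_count(protein: str, epitope: str) -> int:
    return sum(
        1
        for i in range(len(protein) - len(epitope) + 1)
        if protein[i : i + len(epitope)] == epitope
    )


def best_alignment_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Optimal global alignment score by exhaustive recursion (tiny inputs)."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, f(i + 1, j + 1) + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            best = max(best, f(i + 1, j) + gap)
        if j < len(b):
            best = max(best, f(i, j + 1) + gap)
        return best

    return f(0, 0)


def induced_pairwise_score(row_a: str, row_b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Score of the pairwise alignment induced by two rows of an MSA
    (columns gapped in both rows are skipped)."""
    score = 0.0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            score += gap
        else:
            score += match if x == y else mismatch
    return score


def p_distance_oracle(a: str, b: str) -> float:
    sites = [(x, y) for x, y in zip(a, b) if x not in "-X" and y not in "-X"]
    return sum(1 for x, y in sites if x != y) / len(sites)


def tree_path_lengths(tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths of a (rooted representation of an) unrooted tree."""
    tips = list(tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[frozenset((a.name, b.name))] = a.distance(b)
    return out


def random_overlapping_pair(rng: np.random.Generator, read_len=60, overlap=30,
                            n_errors=0, rid="pair") -> tuple[ReadPair, int]:
    """A read pair sharing a planted overlap; returns the pair and the overlap."""
    total = 2 * read_len - overlap
    template = "".join(rng.choice(list("ACGT"), size=total))
    fwd = template[:read_len]
    rev_region = list(template[-read_len:])
    for _ in range(n_errors):
        i = int(rng.integers(read_len))
        rev_region[i] = "ACGT"[(("ACGT".index(rev_region[i])) + 1 + int(rng.integers(3))) % 4]
    rev = revcomp("".join(rev_region))
    q = [40] * read_len
    return ReadPair(rid, fwd, rev, list(q), list(q)), overlap


def pipeline_to_proteins(fwd_reads, rev_reads, sheet):
    """Minimal trim/merge/demux/strip/translate chain used by truth-based tests."""
    records = []
    for f, r in zip(fwd_reads, rev_reads):
        pair = ReadPair(f.id, f.seq, r.seq, list(f.qual), list(r.qual))
        tf = quality_trim(pair.fwd_seq, pair.fwd_qual)
        tr = quality_trim(pair.rev_seq, pair.rev_qual)
        if tf is None or tr is None:
            continue
        pair.fwd_seq, pair.fwd_qual = tf
        pair.rev_seq, pair.rev_qual = tr
        amp = merge_pair(pair)
        if amp is None:
            continue
        genotype = demultiplex(amp, sheet)
        if genotype == "UNASSIGNED":
            continue
        cds = strip_technical(amp)
        if cds is None:
            continue
        records.append(
            ProteinRecord(id=cds.id, genotype=genotype, protein=translate_cds(cds.cds))
        )
    return records
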