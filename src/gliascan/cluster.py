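"""Translation of coding sequences, stop-codon filtering, and exact-identity
protein clustering with the cluster-size confidence filter.

Clustering is at 100% identity, implemented as exact string equality within
a genotype: frequency weighting by cluster size is only well defined when
all members are the same protein.  (Greedy substring absorption, as some
deduplication tools perform at 100% identity, is deliberately not done.)
The size filter keeps clusters with more than 15 members by default, i.e.
``size >= min_members`` with ``min_members = 16``, discarding low-confidence
sequences arising from sequencing errors or PCR stochasticity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_CODON_TO_AA = dict(_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    genotype: str
    protein: str

    def __post_init__(self) -> None:
        bad = set(self.protein) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"record {self.id}: illegal residue(s) {sorted(bad)}")


@dataclass(frozen=True)
class ProteinCluster:
    """A set of identical translated CDSs: shared string, multiplicity, genotype."""

    representative: str
    size: int
    genotype: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if "*" in self.representative:
            raise ValueError("cluster representative contains a stop codon")


def translate_cds(cds: str) -> str:
    """Standard-table translation.

    The trailing length-mod-3 remainder is dropped; any codon containing N
    translates to ``X``; stop codons translate to ``*``.
    """
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            try:
                out.append(_CODON_TO_AA[codon])
            except KeyError:
                raise ValueError(f"invalid codon {codon!r}") from None
    return "".join(out)


def filter_stops(
    records: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], Counter]:
    """Drop proteins containing internal stop codons ('*').

    Returns the retained records and a per-genotype Counter of removals.
    """
    retained: list[ProteinRecord] = []
    removed: Counter = Counter()
    for rec in records:
        if "*" in rec.protein:
            removed[rec.genotype] += 1
        else:
            retained.append(rec)
    return retained, removed


def cluster_identical(
    records: Sequence[ProteinRecord],
) -> dict[str, list[ProteinCluster]]:
    """Cluster stop-free proteins at 100% identity within each genotype.

    Clusters are returned per genotype, ordered by decreasing size then by
    representative string; the sum of sizes equals the record count.
    """
    by_genotype: dict[str, Counter] = defaultdict(Counter)
    for rec in records:
        if "*" in rec.protein:
            raise ValueError(f"record {rec.id}: stop codon in protein; filter first")
        by_genotype[rec.genotype][rec.protein] += 1
    out: dict[str, list[ProteinCluster]] = {}
    for genotype, counts in by_genotype.items():
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[genotype] = [
            ProteinCluster(
                representative=prot,
                size=size,
                genotype=genotype,
                id=f"{genotype}|c{i}|{size}",
            )
            for i, (prot, size) in enumerate(ordered)
        ]
    return out


def filter_clusters(
    clusters: dict[str, list[ProteinCluster]], min_members: int = 16
) -> tuple[dict[str, list[ProteinCluster]], dict[str, tuple[int, int]]]:
    """Keep clusters with ``size >= min_members``.

    Returns the filtered mapping and per-genotype (kept, dropped) counts.
    The default of 16 keeps clusters with *more than 15* members.
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    kept: dict[str, list[ProteinCluster]] = {}
    counts: dict[str, tuple[int, int]] = {}
    for genotype, cl in clusters.items():
        selected = [c for c in cl if c.size >= min_members]
        kept[genotype] = selected
        counts[genotype] = (len(selected), len(cl) - len(selected))
    return kept, counts


def write_representatives_fasta(
    clusters: dict[str, list[ProteinCluster]], path
) -> None:
    """FASTA of cluster representatives; headers ``genotype|cluster_id|size``."""
    with open(path, "w", encoding="utf-8") as fh:
        for genotype in sorted(clusters):
            for c in clusters[genotype]:
                fh.write(f">{c.id}\n{c.representative}\n")
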