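"""Synthetic barcoded paired-end amplicon generator with ground truth.

Emulates the amplicon assay's read anatomy so every downstream stage is
testable offline: each simulated transcript is an in-frame CDS of
``signal peptide (starting with the forward-primer motif MKTF[LP]I) +
variable epitope-bearing domain + reverse-primer binding tail (QPISQQQ)``.
The forward read starts with the genotype's 8-bp barcode followed by the
primer-matching bases; the reverse read is the reverse complement of the
amplicon's 3' end.  A configurable fraction of reads derives from
pseudogene copies carrying an internal stop codon, and substitution errors
are applied i.i.d. per base.  Qualities are Q40, dropped to Q10 where an
error was injected, so quality-aware merging is exercised.

Reads are simulated post-adapter: the first observable base is the barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .constants import (
    GENOTYPE_BARCODES,
    SIGNAL_PEPTIDE,
    TAIL_CODONS,
    TAIL_PROTEIN,
)
from .panel import EpitopePanel

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_BACK_TABLE: dict[str, tuple[str, ...]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _BACK_TABLE.setdefault(aa, [])
    _BACK_TABLE[aa].append(codon)
_BACK_TABLE = {aa: tuple(sorted(cs)) for aa, cs in _BACK_TABLE.items()}
_STOPS = tuple(sorted(_STANDARD.stop_codons))

#: Codon choices for the first six residues, constrained to the degenerate
#: forward primer atgaaracmtttcycatc (M K T F [LP] I).
_PRIMER_CODONS: tuple[tuple[str, ...], ...] = (
    ("ATG",),          # M
    ("AAA", "AAG"),    # K  (aar)
    ("ACA", "ACC"),    # T  (acm)
    ("TTT",),          # F  (ttt)
    None,              # L or P, resolved per template: cyc -> CTC / CCC
    ("ATC",),          # I
)


@dataclass(frozen=True)
class TranscriptProfile:
    """One transcript of a genotype: its mature (variable) domain and its
    relative abundance within the genotype's amplicon pool."""

    core: str
    abundance: float

    def full_template(self) -> str:
        return SIGNAL_PEPTIDE + self.core + TAIL_PROTEIN


@dataclass(frozen=True)
class GenotypeSpec:
    name: str
    barcode: str
    depth: int
    transcript_profiles: tuple[TranscriptProfile, ...]
    pseudogene_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.barcode) != 8 or set(self.barcode) - set("ACGT"):
            raise ValueError(f"{self.name}: barcode must be 8 bases over ACGT")
        if self.depth < 1:
            raise ValueError(f"{self.name}: depth must be >= 1")
        if not self.transcript_profiles:
            raise ValueError(f"{self.name}: no transcript profiles")
        abund = [p.abundance for p in self.transcript_profiles]
        if any(a < 0 for a in abund) or sum(abund) <= 0:
            raise ValueError(f"{self.name}: abundances must be >= 0 with positive sum")
        if not 0 <= self.pseudogene_fraction <= 1:
            raise ValueError(f"{self.name}: pseudogene_fraction outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    read_length: tuple[int, int] = (250, 300)
    substitution_error_rate: float = 0.0
    insert_length_range: tuple[int, int] = (250, 490)

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_error_rate <= 0.2:
            raise ValueError("substitution_error_rate outside [0, 0.2]")
        for lo, hi in (self.read_length, self.insert_length_range):
            if lo > hi or lo < 1:
                raise ValueError("empty or invalid length range")


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: np.ndarray


@dataclass
class GenotypeTruth:
    """Ground truth for one genotype: expected per-epitope occurrences per
    (retained) read, and the pseudogene fraction used."""

    genotype: str
    epitope_abundance: dict[str, float]
    pseudogene_fraction: float


def _scan(core: str, peptide: str) -> int:
    # independent overlap-inclusive scan (kept separate from the pipeline's
    # counter so the generator can serve as its oracle)
    return sum(
        1 for i in range(len(core) - len(peptide) + 1) if core[i : i + len(peptide)] == peptide
    )


def build_transcript(
    template: str, rng: np.random.Generator, pseudogene: bool = False
) -> str:
    """Back-translate a protein template into an in-frame CDS.

    The template must start with the forward-primer motif MKTF[LP]I; those
    six codons are drawn from the primer-compatible set so the CDS's first
    18 nt degenerate-match the forward primer.  If the template ends with
    QPISQQQ, the tail codons are fixed to the reverse-primer-compatible
    choice.  All other codons are uniform over synonymous codons under
    ``rng``.  With ``pseudogene=True`` one internal codon is replaced by a
    stop codon.
    """
    if len(template) < 8:
        raise ValueError("template too short")
    if not (template.startswith("MKTF") and template[4] in "LP" and template[5] == "I"):
        raise ValueError("template must start with the MKTF[LP]I primer motif")
    bad = [aa for aa in template if aa not in _BACK_TABLE]
    if bad:
        raise ValueError(f"no codon for letter(s) {sorted(set(bad))!r}")

    has_tail = template.endswith(TAIL_PROTEIN)
    n_tail = len(TAIL_PROTEIN) if has_tail else 0
    codons: list[str] = []
    for i, aa in enumerate(template):
        if i < 6:
            choices = _PRIMER_CODONS[i]
            if choices is None:
                choices = ("CTC",) if aa == "L" else ("CCC",)
            codons.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0])
        elif has_tail and i >= len(template) - n_tail:
            j = i - (len(template) - n_tail)
            codons.append(TAIL_CODONS[3 * j : 3 * j + 3])
        else:
            choices = _BACK_TABLE[aa]
            codons.append(choices[rng.integers(len(choices))])
    if pseudogene:
        # stop codon goes into the mature domain (not the trimmed signal
        # peptide or primer-constrained tail) so it is observable downstream
        n_sig = len(SIGNAL_PEPTIDE)
        lo = n_sig if template.startswith(SIGNAL_PEPTIDE) and len(template) - n_tail > n_sig else 6
        hi = len(template) - n_tail
        pos = int(rng.integers(lo, hi))
        codons[pos] = _STOPS[rng.integers(len(_STOPS))]
    return "".join(codons)


def _apply_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    qual = np.full(len(seq), 40, dtype=int)
    if rate <= 0:
        return seq, qual
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if not hits.size:
        return seq, qual
    chars = list(seq)
    for i in hits:
        others = [b for b in "ACGT" if b != chars[i]]
        chars[i] = others[rng.integers(3)]
        qual[i] = 10
    return "".join(chars), qual


_RC = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def simulate_reads(
    spec: GenotypeSpec,
    config: SimulationConfig,
    panel: EpitopePanel,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], list[FastqRead], GenotypeTruth]:
    """Simulate ``spec.depth`` read pairs for one genotype.

    Returns forward reads, reverse reads, and the genotype's ground truth
    (panel-epitope occurrences per transcript weighted by abundance).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profiles = spec.transcript_profiles
    cds = [build_transcript(p.full_template(), rng) for p in profiles]
    pseudo_cds = [
        build_transcript(p.full_template(), rng, pseudogene=True) for p in profiles
    ]
    amplicons = [spec.barcode + c for c in cds]
    pseudo_amplicons = [spec.barcode + c for c in pseudo_cds]
    lo, hi = config.insert_length_range
    for p, a in zip(profiles, amplicons):
        if not lo <= len(a) <= hi:
            raise ValueError(
                f"{spec.name}: amplicon length {len(a)} outside insert range "
                f"[{lo}, {hi}] (core of {len(p.core)} aa)"
            )

    abund = np.array([p.abundance for p in profiles], dtype=float)
    probs = abund / abund.sum()
    picks = rng.choice(len(profiles), size=spec.depth, p=probs)
    is_pseudo = rng.random(spec.depth) < spec.pseudogene_fraction
    rlo, rhi = config.read_length
    len_f = rng.integers(rlo, rhi + 1, size=spec.depth)
    len_r = rng.integers(rlo, rhi + 1, size=spec.depth)

    fwd_reads: list[FastqRead] = []
    rev_reads: list[FastqRead] = []
    rate = config.substitution_error_rate
    for i in range(spec.depth):
        amp = (pseudo_amplicons if is_pseudo[i] else amplicons)[picks[i]]
        lf = min(int(len_f[i]), len(amp))
        lr = min(int(len_r[i]), len(amp))
        fseq, fq = _apply_errors(amp[:lf], rate, rng)
        rseq, rq = _apply_errors(_rc(amp[-lr:]), rate, rng)
        rid = f"sim:{spec.barcode}:{i}"
        fwd_reads.append(FastqRead(rid, fseq, fq))
        rev_reads.append(FastqRead(rid, rseq, rq))

    weights = probs
    truth = {
        e.id: float(sum(w * _scan(p.core, e.sequence) for w, p in zip(weights, profiles)))
        for e in panel
    }
    return (
        fwd_reads,
        rev_reads,
        GenotypeTruth(spec.name, truth, spec.pseudogene_fraction),
    )


def write_truth_table(truths: Sequence[GenotypeTruth], path: str | Path) -> None:
    """TSV: genotype, epitope_id, true_relative_abundance (zeros omitted)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genotype\tepitope_id\ttrue_relative_abundance\n")
        for t in truths:
            for eid, value in t.epitope_abundance.items():
                if value > 0:
                    fh.write(f"{t.genotype}\t{eid}\t{value:.10g}\n")


def read_truth_table(path: str | Path) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["genotype", "epitope_id", "true_relative_abundance"]:
            raise ValueError(f"{path}: unexpected truth-table header")
        for line in fh:
            g, eid, v = line.rstrip("\n").split("\t")
            out.setdefault(g, {})[eid] = float(v)
    return out


# --- default study-like genotype compositions ---------------------------------

_PREFIX = "VRVPVPQLQPQNPSQQQPQEQ"
_SUFFIX = "PQQPFPQQ"


def _core(blocks: Sequence[str]) -> str:
    # repetitive-domain-like scaffold; lengths land inside the 250-490 bp
    # merged-amplicon envelope once signal peptide, tail and barcode are added
    return _PREFIX + "QQ".join(blocks) + _SUFFIX


# Epitope building blocks by panel id (canonical + a few variants).
_B = {
    "a1a": "PFPQPQLPY",
    "a1b": "PYPQPQLPY",
    "a2": "PQPQLPYPQ",
    "a3": "FRPQQPYPQ",
    "p31": "LGQQQPFPPQQPY",
    "a1a_v1": "PFPQPELPY",
    "a2_v4": "PQSQLPYPQ",
    "a2_v7": "PQPQLSYPQ",
    "a3_v1": "FRPQQPYPE",
    "a3_v3": "FRPEQPYPQ",
    "p31_v1": "LGQQQPFPPQQPF",
    "p44_55": "PQPQPFPSQQPY",
    "g1": "PQQSFPEQQ",
    "ave1b": "PYPEQEQPF",
}

# Per-genotype transcript recipes: lists of (block ids, abundance).  The mix
# loosely mirrors the study's narrative (one accession rich in every toxic
# epitope, the Ae. crassa accessions poor in them) without reproducing it.
_RECIPES: dict[str, list[tuple[list[str], float]]] = {
    "Ae. juvenalis 'AE 537'": [
        (["p31", "a1a", "a2", "a3", "p31"], 0.4),
        (["p31", "a3", "a3_v1", "p44_55", "a2"], 0.3),
        (["a1b", "a2", "p31_v1", "a3", "g1"], 0.2),
        (["a1a_v1", "a2_v7", "p31", "a3"], 0.1),
    ],
    "Ae. juvenalis 'AE 1495'": [
        (["p31", "a1a", "a2", "p31", "a1a"], 0.45),
        (["p31", "a2", "a2", "p44_55", "g1"], 0.3),
        (["a1a", "a2_v4", "p31_v1", "a3_v3"], 0.25),
    ],
    "Ae. tauschii 'AE 1600'": [
        (["p31", "a1a", "a1b", "a2", "a3"], 0.4),
        (["a3", "a2", "p31", "p44_55"], 0.35),
        (["a1b", "a3_v1", "a2_v7", "g1", "p31"], 0.25),
    ],
    "Ae. tauschii 'AE 1211'": [
        (["p31", "a1b", "a2", "a3", "a3"], 0.4),
        (["a1a", "a2", "p31", "a3_v3"], 0.35),
        (["p31_v1", "a2_v4", "a3", "ave1b"], 0.25),
    ],
    "Ae. cylindrica 'AE 1594'": [
        (["p31", "a1a", "a2", "a3"], 0.5),
        (["a1a_v1", "a2_v4", "p31", "a3"], 0.3),
        (["a1b", "a2", "g1", "p44_55"], 0.2),
    ],
    "Ae. cylindrica 'AE 1658'": [
        (["p31", "a1a", "a2"], 0.5),
        (["a1a_v1", "a2_v4", "p31_v1"], 0.3),
        (["a2_v7", "g1", "ave1b", "a3"], 0.2),
    ],
    "Ae. ventricosa 'AE 1511'": [
        (["p31", "a1a", "a1b", "a2", "a3"], 0.4),
        (["a1b", "a2", "a3", "p31", "a1a"], 0.3),
        (["a3", "a3_v1", "a2", "p31", "a1b"], 0.2),
        (["p44_55", "a2_v7", "a1a", "a3"], 0.1),
    ],
    "Ae. ventricosa 'AE 730'": [
        (["p31", "a1b", "a2", "a3"], 0.45),
        (["a1a", "a3", "p31", "g1"], 0.3),
        (["a3_v1", "a2_v4", "p44_55", "ave1b"], 0.25),
    ],
    "Ae. crassa 'TA1873'": [
        (["p31", "a1a", "a2"], 0.5),
        (["p31", "g1", "ave1b", "a1a"], 0.3),
        (["a2_v4", "p31_v1", "a3"], 0.2),
    ],
    "Ae. crassa 'AE 815'": [
        (["p31", "a1a", "a2", "g1"], 0.5),
        (["p31_v1", "a3", "ave1b"], 0.3),
        (["a1a", "a2_v7", "p44_55"], 0.2),
    ],
}


def default_genotype_specs(
    depth: int = 20000, pseudogene_fraction: float = 0.3, n_genotypes: int = 10
) -> list[GenotypeSpec]:
    """Study-condition genotype specs: the ten accessions with their
    published barcodes, tens of thousands of read pairs each, and a
    pseudogene fraction reflecting the prevalence of internally-stopped
    alpha-gliadin copies."""
    if not 1 <= n_genotypes <= len(GENOTYPE_BARCODES):
        raise ValueError("n_genotypes outside the available accession list")
    specs = []
    for name, barcode in GENOTYPE_BARCODES[:n_genotypes]:
        profiles = tuple(
            TranscriptProfile(core=_core([_B[b] for b in blocks]), abundance=ab)
            for blocks, ab in _RECIPES[name]
        )
        specs.append(
            GenotypeSpec(
                name=name,
                barcode=barcode,
                depth=depth,
                transcript_profiles=profiles,
                pseudogene_fraction=pseudogene_fraction,
            )
        )
    return specs


def simulate_dataset(
    specs: Sequence[GenotypeSpec],
    config: SimulationConfig,
    panel: EpitopePanel,
) -> tuple[list[FastqRead], list[FastqRead], list[GenotypeTruth]]:
    """Simulate a multiplexed dataset (all genotypes pooled into one pair of
    read streams) from a single seeded generator."""
    barcodes = [s.barcode for s in specs]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcode collision between genotypes")
    rng = np.random.default_rng(config.seed)
    fwd: list[FastqRead] = []
    rev: list[FastqRead] = []
    truths: list[GenotypeTruth] = []
    for spec in specs:
        f, r, t = simulate_reads(spec, config, panel, rng=rng)
        fwd.extend(f)
        rev.extend(r)
        truths.append(t)
    return fwd, rev, truths
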