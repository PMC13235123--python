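"""Shared sequence constants of the alpha-gliadin amplicon assay.

The amplified region is the first variable (repetitive) domain of
alpha-gliadin, bracketed by a degenerate forward primer sitting on the
MKTF[LP]I start of the signal peptide and a universal degenerate reverse
primer on the PISQQQ motif.  Forward fusion primers carry an 8-bp
genotype barcode immediately 5' of the gene-specific segment.
"""

from __future__ import annotations

#: Degenerate gene-specific forward primer (AlphaF); encodes MKTF[LP]I.
FORWARD_PRIMER = "ATGAARACMTTTCYCATC"

#: Degenerate universal reverse primer (AlphaR); binds the PISQQQ-coding region.
REVERSE_PRIMER = "CTGCTGCTGTGAAATTRGWT"

#: Barcode length on the forward read.
BARCODE_LENGTH = 8

#: Amino acids of the highly immunogenic alpha-gliadin 33-mer region
#: (reference protein AFX69628.1) which carries six copies of the
#: DQ2.5-glia-alpha1/alpha2 epitopes.
THIRTY_THREE_MER = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQP"

#: Signal peptide used by the synthetic transcript builder.  Its first six
#: residues (MKTFLI) are the forward-primer motif; the remainder is a
#: plausible hydrophobic leader.  The pipeline trims this many codons after
#: anchoring the frame on the primer ATG.
SIGNAL_PEPTIDE = "MKTFLILALLAIVATTATTA"
SIGNAL_PEPTIDE_CODONS = len(SIGNAL_PEPTIDE)

#: C-terminal motif covered by the reverse primer.  The trailing codons are
#: fixed so the coding strand degenerate-matches the reverse complement of
#: REVERSE_PRIMER (the primer starts at the second base of the CAA codon).
TAIL_PROTEIN = "QPISQQQ"
TAIL_CODONS = "CAACCAATTTCACAGCAGCAG"

#: Genotype / 8-bp barcode assignments of the ten Aegilops accessions
#: (five D-genome species, two accessions each).
GENOTYPE_BARCODES: tuple[tuple[str, str], ...] = (
    ("Ae. juvenalis 'AE 537'", "TTCGGAGT"),
    ("Ae. juvenalis 'AE 1495'", "ACTCATTT"),
    ("Ae. tauschii 'AE 1600'", "GGGATCCG"),
    ("Ae. tauschii 'AE 1211'", "CAAGATAA"),
    ("Ae. cylindrica 'AE 1594'", "GGACAACG"),
    ("Ae. cylindrica 'AE 1658'", "AGCGAGCT"),
    ("Ae. ventricosa 'AE 1511'", "CTGCACGT"),
    ("Ae. ventricosa 'AE 730'", "GCACTAGT"),
    ("Ae. crassa 'TA1873'", "TACTGAGA"),
    ("Ae. crassa 'AE 815'", "ATCGTACT"),
)

#: IUPAC nucleotide codes -> set of matching unambiguous bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) DNA string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"not a DNA/IUPAC base: {exc}") from exc


#: Reverse complement of the reverse primer, as it appears on the coding
#: strand at the 3' end of every amplicon.
REVERSE_PRIMER_RC = reverse_complement(REVERSE_PRIMER)
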