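"""Read preprocessing: quality trimming, overlap merging, demultiplexing,
and stripping of technical sequence down to in-frame coding sequences.

The amplicon anatomy (5' to 3' on the forward strand) is::

    [8-bp barcode][degenerate forward primer = first 6 codons of the signal
    peptide][rest of signal peptide][variable alpha-gliadin domain][reverse
    primer binding region]

Merging recovers the full amplicon from a forward/reverse pair by scoring
every candidate overlap; demultiplexing is an exact match of the first 8
bases against the sample sheet; stripping removes barcode, primers and the
signal peptide, anchoring the reading frame at the forward primer's ATG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    BARCODE_LENGTH,
    FORWARD_PRIMER,
    IUPAC_CODES,
    REVERSE_PRIMER,
    SIGNAL_PEPTIDE_CODONS,
    reverse_complement,
)

UNASSIGNED = "UNASSIGNED"

_DNA5 = frozenset("ACGTN")


@dataclass
class ReadPair:
    """A forward/reverse read pair with Phred qualities."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: Sequence[int]
    rev_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        for s in (self.fwd_seq, self.rev_seq):
            if set(s) - _DNA5:
                raise ValueError(f"read {self.id}: non-ACGTN base in sequence")


@dataclass
class MergedAmplicon:
    """A merged (full-length) amplicon, optionally assigned to a genotype."""

    id: str
    seq: str
    qual: np.ndarray
    genotype: str = UNASSIGNED


@dataclass
class CDSRecord:
    """An in-frame coding sequence after technical-sequence removal.

    ``provenance`` records the half-open offsets (on the merged amplicon) of
    each removed element.
    """

    id: str
    genotype: str
    cds: str
    provenance: dict = field(default_factory=dict)


def quality_trim(
    seq: str,
    qual: Sequence[int],
    window_size: int = 4,
    mean_q: float = 20,
    min_len: int = 36,
) -> tuple[str, Sequence[int]] | None:
    """Sliding-window 3' quality trim.

    Scans left to right; truncates at the start of the first full window
    whose mean quality falls below ``mean_q``.  Returns ``None`` (DISCARD)
    when the surviving read is shorter than ``min_len``.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = len(seq)
    cut = n
    if n >= window_size:
        q = np.asarray(qual, dtype=float)
        csum = np.concatenate(([0.0], np.cumsum(q)))
        means = (csum[window_size:] - csum[:-window_size]) / window_size
        bad = np.nonzero(means < mean_q)[0]
        if bad.size:
            cut = int(bad[0])
    if cut < min_len:
        return None
    if cut == n:
        return seq, qual
    return seq[:cut], qual[:cut]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> MergedAmplicon | None:
    """Merge a read pair by exhaustive overlap scoring.

    The reverse read is reverse-complemented, then every candidate overlap
    length ``L`` from ``min(len_f, len_r)`` down to ``min_overlap`` is scored.
    Candidates whose mismatch density (mismatches / L) exceeds
    ``max_mismatch_density`` are rejected; among the rest the overlap
    maximising ``matches - mismatches`` wins, ties going to the larger ``L``.
    Overlap consensus takes the base with the higher Phred score (ties to the
    forward read) and the max of the two qualities.  Returns ``None`` on
    merge failure.  ``N`` matches nothing, including another ``N``.
    """
    if not pair.fwd_seq or not pair.rev_seq:
        raise ValueError(f"read {pair.id}: empty read")
    fwd = pair.fwd_seq
    rc_rev = reverse_complement(pair.rev_seq)
    rc_qual = np.asarray(pair.rev_qual)[::-1]
    lf, lr = len(fwd), len(rc_rev)
    max_l = min(lf, lr)
    if max_l < min_overlap:
        return None

    f = _encode(fwd)
    r = _encode(rc_rev)
    # matches(L) = correlation of one-hot encodings at shift lf - L
    matches_by_shift = np.zeros(lf + lr - 1)
    for b in range(4):
        fb = (f == b).astype(np.float64)
        rb = (r == b).astype(np.float64)
        matches_by_shift += np.correlate(fb, rb, mode="full")
    # np.correlate(a, v, 'full')[k] = sum_n a[n + k - (len(v)-1)] * v[n]
    best_l = -1
    best_score = None
    for L in range(max_l, min_overlap - 1, -1):
        shift = lf - L
        m = int(round(matches_by_shift[shift + lr - 1]))
        mismatches = L - m
        if mismatches / L > max_mismatch_density:
            continue
        score = m - mismatches
        if best_score is None or score > best_score:
            best_score = score
            best_l = L
    if best_l < 0:
        return None

    L = best_l
    fq = np.asarray(pair.fwd_qual)
    f_over = np.frombuffer(fwd[lf - L :].encode(), dtype=np.uint8)
    r_over = np.frombuffer(rc_rev[:L].encode(), dtype=np.uint8)
    fq_over = fq[lf - L :]
    rq_over = rc_qual[:L]
    take_rev = rq_over > fq_over
    cons = np.where(take_rev, r_over, f_over)
    cons_q = np.maximum(fq_over, rq_over)
    merged_seq = fwd[: lf - L] + cons.tobytes().decode() + rc_rev[L:]
    merged_qual = np.concatenate((fq[: lf - L], cons_q, rc_qual[L:]))
    return MergedAmplicon(id=pair.id, seq=merged_seq, qual=merged_qual)


def load_sample_sheet(path: str | Path) -> dict[str, str]:
    """Load a ``genotype<TAB>barcode`` sample sheet; returns barcode -> genotype.

    Duplicate barcodes or barcodes that are not 8 ACGT letters are errors.
    An optional header line ``genotype\\tbarcode`` is accepted.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            genotype, barcode = parts[0].strip(), parts[1].strip().upper()
            if (genotype, barcode) == ("genotype", "BARCODE"):
                continue
            if len(barcode) != BARCODE_LENGTH or set(barcode) - set("ACGT"):
                raise ValueError(
                    f"{path}:{lineno}: barcode must be 8 ACGT letters, got {barcode!r}"
                )
            if barcode in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate barcode {barcode}")
            mapping[barcode] = genotype
    if not mapping:
        raise ValueError(f"{path}: empty sample sheet")
    return mapping


def demultiplex(amplicon: MergedAmplicon, sample_sheet: Mapping[str, str]) -> str:
    """Assign an amplicon to a genotype by exact match of its first 8 bases.

    Returns the genotype (or ``UNASSIGNED``) and records it on the amplicon.
    """
    barcode = amplicon.seq[:BARCODE_LENGTH]
    amplicon.genotype = sample_sheet.get(barcode, UNASSIGNED)
    return amplicon.genotype


def match_degenerate(primer: str, seq: str, offset: int) -> bool:
    """True iff ``seq[offset:offset+len(primer)]`` is contained in the primer's
    IUPAC code sets position by position.  A primer running past the end of
    the sequence does not match; a negative or out-of-sequence offset is an
    error."""
    if offset < 0 or offset > len(seq):
        raise ValueError(f"offset {offset} out of range for length {len(seq)}")
    if offset + len(primer) > len(seq):
        return False
    for i, code in enumerate(primer.upper()):
        try:
            allowed = IUPAC_CODES[code]
        except KeyError:
            raise ValueError(f"not an IUPAC code: {code!r}") from None
        if seq[offset + i] not in allowed:
            return False
    return True


def strip_technical(
    amplicon: MergedAmplicon,
    fwd_primer: str = FORWARD_PRIMER,
    rev_primer: str = REVERSE_PRIMER,
    signal_peptide_codons: int = SIGNAL_PEPTIDE_CODONS,
    rev_search_window: int = 40,
) -> CDSRecord | None:
    """Remove barcode, primers and signal peptide; anchor the reading frame.

    The forward primer must match immediately after the 8-bp barcode (its
    first base is the A of the signal peptide's start codon, which fixes the
    frame).  The reverse primer's reverse complement is located within the
    last ``rev_search_window`` bases (rightmost match wins) and everything
    from it onward is truncated.  The first ``signal_peptide_codons`` codons
    are then removed.  Returns ``None`` when either primer cannot be found.
    """
    seq = amplicon.seq
    if not match_degenerate(fwd_primer, seq, BARCODE_LENGTH):
        return None
    rc = reverse_complement(rev_primer)
    plen = len(rc)
    lo = max(BARCODE_LENGTH, len(seq) - rev_search_window)
    rev_start = None
    for start in range(len(seq) - plen, lo - 1, -1):
        if match_degenerate(rc, seq, start):
            rev_start = start
            break
    if rev_start is None:
        return None
    signal_nt = 3 * signal_peptide_codons
    cds_start = BARCODE_LENGTH + signal_nt
    if cds_start >= rev_start:
        return None
    cds = seq[cds_start:rev_start]
    return CDSRecord(
        id=amplicon.id,
        genotype=amplicon.genotype,
        cds=cds,
        provenance={
            "barcode": (0, BARCODE_LENGTH),
            "fwd_primer": (BARCODE_LENGTH, BARCODE_LENGTH + len(fwd_primer)),
            "signal_peptide": (BARCODE_LENGTH, cds_start),
            "rev_primer": (rev_start, rev_start + plen),
        },
    )
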