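"""FASTQ / FASTA / TSV helpers (Phred+33; transparent gzip on read and write)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .preprocess import ReadPair
from .simulate import FastqRead


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime so identical runs produce byte-identical archives
            return gzip.open(path, mode, mtime=0)
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""), encoding="utf-8")


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    """Write 4-line FASTQ records (Phred+33). Returns the record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with _open_text(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield FastqRead(
                id=rec.id,
                seq=str(rec.seq).upper(),
                qual=np.asarray(rec.letter_annotations["phred_quality"], dtype=int),
            )


def read_pairs(fwd_path: str | Path, rev_path: str | Path) -> Iterator[ReadPair]:
    """Iterate paired records from two FASTQ files; ids must correspond."""
    for f, r in zip(read_fastq(fwd_path), read_fastq(rev_path), strict=True):
        if f.id != r.id:
            raise ValueError(f"read pairing mismatch: {f.id} vs {r.id}")
        yield ReadPair(
            id=f.id, fwd_seq=f.seq, rev_seq=r.seq, fwd_qual=f.qual, rev_qual=r.qual
        )


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_sample_sheet(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    """``genotype<TAB>barcode`` sheet."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genotype\tbarcode\n")
        for genotype, barcode in pairs:
            fh.write(f"{genotype}\t{barcode}\n")
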