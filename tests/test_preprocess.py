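import numpy as np
import pytest

from helpers import (
    brute_merge,
    brute_quality_trim,
    pipeline_to_proteins,
    random_overlapping_pair,
    revcomp,
)

from gliascan.constants import GENOTYPE_BARCODES
from gliascan.preprocess import (
    ReadPair,
    UNASSIGNED,
    demultiplex,
    load_sample_sheet,
    match_degenerate,
    merge_pair,
    quality_trim,
    strip_technical,
)
from gliascan.simulate import SimulationConfig, simulate_reads, default_genotype_specs


# --- quality_trim ---------------------------------------------------------


def test_trim_keeps_clean_read():
    seq = "ACGT" * 20
    qual = [40] * 80
    assert quality_trim(seq, qual) == (seq, qual)


def test_trim_truncates_before_low_quality_tail():
    seq = "A" * 50 + "C" * 50
    qual = [40] * 50 + [2] * 50
    trimmed = quality_trim(seq, qual)
    assert trimmed is not None
    assert set(trimmed[0]) == {"A"}  # cut lands before the Q2 tail
    assert min(trimmed[1]) == 40
    assert trimmed == brute_quality_trim(seq, qual)


def test_trim_discards_short_read():
    assert quality_trim("A" * 20, [40] * 20, min_len=36) is None


def test_trim_agrees_with_window_scan_oracle():
    rng = np.random.default_rng(4)
    for _ in range(200):
        n = int(rng.integers(5, 120))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        qual = list(rng.integers(2, 41, size=n))
        assert quality_trim(seq, qual) == brute_quality_trim(seq, qual)


# --- merge_pair -----------------------------------------------------------


def test_merge_exact_overlap_length():
    rng = np.random.default_rng(0)
    pair, overlap = random_overlapping_pair(rng, read_len=80, overlap=50)
    merged = merge_pair(pair)
    assert merged is not None
    assert len(merged.seq) == 80 + 80 - 50


def test_merge_fails_without_shared_window():
    pair = ReadPair("x", "A" * 60, "A" * 60, [40] * 60, [40] * 60)
    # rev is revcomp'd to T*60: no overlap passes the density cap
    assert merge_pair(pair) is None


def test_merge_empty_read_is_error():
    with pytest.raises(ValueError):
        merge_pair(ReadPair("x", "", "ACGT", [], [40] * 4))


def test_merge_consensus_takes_higher_quality_base():
    # single mismatch in a 20-base overlap; reverse read has higher quality
    fwd = "A" * 30
    rev_region = "A" * 10 + "C" + "A" * 9  # aligns to fwd[10:30]
    rev = revcomp(rev_region)
    fq = [40] * 30
    rq = [41] * 20
    merged = merge_pair(ReadPair("x", fwd, rev, fq, rq))
    assert merged.seq[20] == "C"
    # tie -> forward base wins
    merged2 = merge_pair(ReadPair("x", fwd, rev, fq, [40] * 20))
    assert merged2.seq[20] == "A"


def test_merge_agrees_with_exhaustive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(300):
        overlap = int(rng.integers(10, 45))
        n_err = int(rng.integers(0, 4))
        pair, _ = random_overlapping_pair(rng, read_len=55, overlap=overlap, n_errors=n_err)
        expected = brute_merge(pair)
        got = merge_pair(pair)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert len(got.seq) == 55 + 55 - expected


# --- demultiplex / sample sheet -------------------------------------------


@pytest.fixture()
def sheet():
    return {barcode: name for name, barcode in GENOTYPE_BARCODES}


def _amplicon(seq):
    from gliascan.preprocess import MergedAmplicon

    return MergedAmplicon(id="x", seq=seq, qual=np.full(len(seq), 40))


def test_demultiplex_published_barcodes(sheet):
    assert demultiplex(_amplicon("TTCGGAGT" + "ACGT" * 10), sheet) == "Ae. juvenalis 'AE 537'"
    assert demultiplex(_amplicon("GGGATCCG" + "ACGT" * 10), sheet) == "Ae. tauschii 'AE 1600'"


def test_demultiplex_unknown_barcode_unassigned(sheet):
    assert demultiplex(_amplicon("AAAAAAAA" + "ACGT" * 10), sheet) == UNASSIGNED


def test_demultiplex_partitions_reads(sheet, panel):
    specs = default_genotype_specs(depth=30, pseudogene_fraction=0.0)
    from gliascan.simulate import simulate_dataset

    fwd, rev, _ = simulate_dataset(specs, SimulationConfig(seed=13), panel)
    records = pipeline_to_proteins(fwd, rev, sheet)
    assert len(records) == 300
    by_g = {}
    for r in records:
        by_g.setdefault(r.genotype, []).append(r.id)
    assert sum(len(v) for v in by_g.values()) == 300
    assert len(by_g) == 10


def test_sample_sheet_duplicate_barcode_is_error(tmp_path):
    p = tmp_path / "sheet.tsv"
    p.write_text("g1\tTTCGGAGT\ng2\tTTCGGAGT\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_sample_sheet(p)


# --- match_degenerate ------------------------------------------------------


@pytest.mark.parametrize(
    "primer,seq,offset,expected",
    [
        ("atgaaracmtttcycatc", "ATGAAGACATTTCTCATC", 0, True),
        ("atgaaracmtttcycatc", "ATGAACACATTTCTCATC", 0, False),
        ("NNNN", "GCTA", 0, True),
    ],
)
def test_match_degenerate_iupac(primer, seq, offset, expected):
    assert match_degenerate(primer.upper(), seq, offset) is expected


def test_match_degenerate_offset_out_of_range():
    with pytest.raises(ValueError):
        match_degenerate("ATG", "ACGT", -1)


def test_match_degenerate_overrun_is_no_match():
    assert match_degenerate("ATGC", "ATG", 0) is False


# --- strip_technical --------------------------------------------------------


def test_strip_recovers_mature_domain(panel):
    spec = default_genotype_specs(depth=100, pseudogene_fraction=0.0, n_genotypes=1)[0]
    fwd, rev, _ = simulate_reads(spec, SimulationConfig(seed=21), panel)
    records = pipeline_to_proteins(fwd, rev, {spec.barcode: spec.name})
    cores = {p.core for p in spec.transcript_profiles}
    assert len(records) == 100
    assert {r.protein for r in records} <= cores


def test_strip_fails_without_reverse_primer():
    from gliascan.preprocess import MergedAmplicon
    from gliascan.constants import FORWARD_PRIMER

    seq = "TTCGGAGT" + "ATGAAGACATTTCTCATC" + "ACGT" * 40
    amp = MergedAmplicon(id="x", seq=seq, qual=np.full(len(seq), 40), genotype="g")
    assert strip_technical(amp) is None


def test_strip_provenance_offsets_match_anatomy(panel):
    spec = default_genotype_specs(depth=20, pseudogene_fraction=0.0, n_genotypes=1)[0]
    fwd, rev, _ = simulate_reads(spec, SimulationConfig(seed=22), panel)
    from gliascan.preprocess import merge_pair as mp

    for f, r in zip(fwd, rev):
        pair = ReadPair(f.id, f.seq, r.seq, list(f.qual), list(r.qual))
        amp = merge_pair(pair)
        amp.genotype = spec.name
        cds = strip_technical(amp)
        assert cds.provenance["barcode"] == (0, 8)
        assert cds.provenance["fwd_primer"] == (8, 26)
        assert cds.provenance["signal_peptide"] == (8, 8 + 60)
        start, end = cds.provenance["rev_primer"]
        assert end == len(amp.seq) and end - start == 20
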