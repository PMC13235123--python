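import numpy as np
import pytest

from helpers import pipeline_to_proteins

from gliascan.cluster import filter_stops, translate_cds
from gliascan.constants import FORWARD_PRIMER, SIGNAL_PEPTIDE, TAIL_PROTEIN
from gliascan.io import write_fastq
from gliascan.preprocess import match_degenerate
from gliascan.simulate import (
    GenotypeSpec,
    SimulationConfig,
    TranscriptProfile,
    build_transcript,
    default_genotype_specs,
    read_truth_table,
    simulate_dataset,
    simulate_reads,
    write_truth_table,
    GenotypeTruth,
)

TEMPLATE = SIGNAL_PEPTIDE + "VRVPVPQLQPFPQPQLPYPQPQLPYPQQPFP" * 2 + TAIL_PROTEIN


def test_build_transcript_matches_forward_primer():
    rng = np.random.default_rng(0)
    cds = build_transcript(TEMPLATE, rng)
    assert match_degenerate(FORWARD_PRIMER, cds, 0)
    assert translate_cds(cds) == TEMPLATE


def test_build_transcript_deterministic_under_seed():
    a = build_transcript(TEMPLATE, np.random.default_rng(42))
    b = build_transcript(TEMPLATE, np.random.default_rng(42))
    assert a == b


def test_build_transcript_pseudogene_has_internal_stop():
    cds = build_transcript(TEMPLATE, np.random.default_rng(1), pseudogene=True)
    protein = translate_cds(cds)
    assert "*" in protein[1:-1]
    # the stop never lands in the trimmed signal peptide or the primer tail
    assert "*" not in protein[: len(SIGNAL_PEPTIDE)]
    assert "*" not in protein[-len(TAIL_PROTEIN):]


def test_build_transcript_requires_primer_motif():
    with pytest.raises(ValueError, match="MKTF"):
        build_transcript("MAAAAAAAAAAA", np.random.default_rng(0))


def _mini_spec(name="G1", barcode="TTCGGAGT", depth=100, pf=0.0):
    core = "VRVPVPQLQPQNPSQQQPQEQ" + "PFPQPQLPYQQPQPQLPYPQQQLGQQQPFPPQQPY" + "PQQPFPQQ"
    return GenotypeSpec(
        name=name,
        barcode=barcode,
        depth=depth,
        transcript_profiles=(TranscriptProfile(core, 1.0),),
        pseudogene_fraction=pf,
    )


def test_read_count_equals_depth(panel):
    spec = _mini_spec(depth=137)
    fwd, rev, truth = simulate_reads(spec, SimulationConfig(seed=3), panel)
    assert len(fwd) == len(rev) == 137
    assert truth.genotype == "G1"


def test_depth_zero_rejected():
    with pytest.raises(ValueError, match="depth"):
        _mini_spec(depth=0)


def test_noiseless_reads_merge_and_demultiplex_losslessly(panel):
    spec = _mini_spec(depth=100)
    fwd, rev, _ = simulate_reads(spec, SimulationConfig(seed=5), panel)
    records = pipeline_to_proteins(fwd, rev, {spec.barcode: spec.name})
    assert len(records) == 100
    assert {r.genotype for r in records} == {spec.name}
    # noiseless round trip recovers the mature domain exactly
    assert {r.protein for r in records} == {spec.transcript_profiles[0].core}


def test_pseudogene_fraction_one_leaves_no_cds(panel):
    spec = _mini_spec(depth=60, pf=1.0)
    fwd, rev, _ = simulate_reads(spec, SimulationConfig(seed=5), panel)
    records = pipeline_to_proteins(fwd, rev, {spec.barcode: spec.name})
    retained, removed = filter_stops(records)
    assert retained == []
    assert removed[spec.name] == len(records) == 60


def test_two_barcodes_no_cross_assignment(panel):
    s1 = _mini_spec("Ae. juvenalis 'AE 537'", "TTCGGAGT", depth=50)
    s2 = _mini_spec("Ae. juvenalis 'AE 1495'", "ACTCATTT", depth=50)
    fwd, rev, _ = simulate_dataset([s1, s2], SimulationConfig(seed=9), panel)
    sheet = {s1.barcode: s1.name, s2.barcode: s2.name}
    records = pipeline_to_proteins(fwd, rev, sheet)
    by_read_prefix = {r.id: r.genotype for r in records}
    for rid, genotype in by_read_prefix.items():
        barcode = rid.split(":")[1]
        assert sheet[barcode] == genotype


def test_barcode_collision_is_error(panel):
    s1 = _mini_spec("A", "TTCGGAGT")
    s2 = _mini_spec("B", "TTCGGAGT")
    with pytest.raises(ValueError, match="collision"):
        simulate_dataset([s1, s2], SimulationConfig(seed=0), panel)


def test_identical_seed_gives_byte_identical_fastq(panel, tmp_path):
    spec = _mini_spec(depth=40)
    for tag in ("a", "b"):
        fwd, rev, _ = simulate_reads(
            spec, SimulationConfig(seed=77, substitution_error_rate=0.01), panel
        )
        write_fastq(fwd, tmp_path / f"{tag}_R1.fastq")
        write_fastq(rev, tmp_path / f"{tag}_R2.fastq")
    for r in ("R1", "R2"):
        assert (tmp_path / f"a_{r}.fastq").read_bytes() == (
            tmp_path / f"b_{r}.fastq"
        ).read_bytes()


def test_error_rate_marks_quality(panel):
    spec = _mini_spec(depth=30)
    fwd, _, _ = simulate_reads(
        spec, SimulationConfig(seed=2, substitution_error_rate=0.05), panel
    )
    quals = np.concatenate([r.qual for r in fwd])
    assert set(np.unique(quals)) <= {10, 40}
    assert (quals == 10).mean() == pytest.approx(0.05, abs=0.01)


def test_truth_table_round_trip(tmp_path):
    truths = [GenotypeTruth("G1", {"a1a": 1.0, "a2": 0.25, "a3": 0.0}, 0.3)]
    path = tmp_path / "truth.tsv"
    write_truth_table(truths, path)
    back = read_truth_table(path)
    assert back == {"G1": {"a1a": 1.0, "a2": 0.25}}  # zero rows omitted


def test_truth_table_empty_is_header_only(tmp_path):
    path = tmp_path / "truth.tsv"
    write_truth_table([], path)
    assert path.read_text().strip() == "genotype\tepitope_id\ttrue_relative_abundance"


def test_default_specs_use_published_barcodes():
    specs = default_genotype_specs(depth=10, n_genotypes=10)
    barcodes = {s.barcode for s in specs}
    assert len(barcodes) == 10
    assert "TTCGGAGT" in barcodes and "GGGATCCG" in barcodes
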