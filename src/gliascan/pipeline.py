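"""End-to-end orchestration: config, stage accounting, report bundle.

``run_pipeline`` wires preprocessing -> translation/clustering -> epitope
quantification -> toxicity scoring -> consensus phylogeny and writes a
reproducible report bundle (frequency matrices, toxicity report, Newick
tree, stage counts, manifest).  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import (
    ProteinRecord,
    cluster_identical,
    filter_clusters,
    filter_stops,
    translate_cds,
    write_representatives_fasta,
)
from .constants import SIGNAL_PEPTIDE_CODONS
from .io import read_pairs, write_fasta, write_fastq, write_sample_sheet
from .panel import EpitopePanel, load_panel, packaged_panel
from .phylo import (
    align_center_star,
    bootstrap_support,
    genotype_consensi,
    p_distance_matrix,
    write_newick,
)
from .preprocess import (
    UNASSIGNED,
    demultiplex,
    load_sample_sheet,
    merge_pair,
    quality_trim,
    strip_technical,
)
from .quantify import FrequencyMatrix
from .simulate import (
    SimulationConfig,
    default_genotype_specs,
    simulate_dataset,
    write_truth_table,
)
from .toxicity import toxicity_reports, toxicity_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    fwd_fastq: Path
    rev_fastq: Path
    sample_sheet: Path
    out_dir: Path
    panel: Path | None = None  # None -> packaged synthetic panel
    window_size: int = 4
    mean_q: float = 20
    min_len: int = 36
    min_overlap: int = 10
    max_mismatch_density: float = 0.25
    signal_peptide_codons: int = SIGNAL_PEPTIDE_CODONS
    min_members: int = 16
    scale: float = 10000
    toxicity_input: str = "normalized"
    depth_denominator: str = "retained"  # or "merged"
    k_top: int = 10
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fwd_fastq", "rev_fastq", "sample_sheet", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.panel is not None:
            self.panel = Path(self.panel)

    def validate(self) -> None:
        for name in ("fwd_fastq", "rev_fastq", "sample_sheet"):
            p = getattr(self, name)
            if not p.exists():
                raise ConfigError(f"{name}: file not found: {p}")
        if self.panel is not None and not self.panel.exists():
            raise ConfigError(f"panel: file not found: {self.panel}")
        if self.toxicity_input not in ("normalized", "raw"):
            raise ConfigError("toxicity_input must be 'normalized' or 'raw'")
        if self.depth_denominator not in ("retained", "merged"):
            raise ConfigError("depth_denominator must be 'retained' or 'merged'")


_INT_KEYS = {
    "window_size", "min_len", "min_overlap", "signal_peptide_codons",
    "min_members", "k_top", "n_reps", "seed",
}
_FLOAT_KEYS = {"mean_q", "max_mismatch_density", "scale"}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Flat ``key = value`` config file; '#' comments; overrides win."""
    values: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            else:
                values[key] = value
    values.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def retained_from_accounting(translated: int, stop_removed: int) -> int:
    """Stop-free CDS count from the accounting identity
    ``retained = translated - stop_removed``."""
    if translated < 0 or stop_removed < 0 or stop_removed > translated:
        raise ValueError("inconsistent read accounting")
    return translated - stop_removed


@dataclass
class StageCounts:
    """Per-stage record accounting.

    Pre-demultiplexing stages (input pairs, post-trim, merged) are pooled
    under ``__all__``; genotype attribution starts at barcode assignment.
    """

    input_pairs: int = 0
    post_trim: int = 0
    merged: int = 0
    unassigned: int = 0
    assigned: Counter = field(default_factory=Counter)
    stripped: Counter = field(default_factory=Counter)
    translated: Counter = field(default_factory=Counter)
    stop_removed: Counter = field(default_factory=Counter)
    retained: Counter = field(default_factory=Counter)
    clusters: Counter = field(default_factory=Counter)
    clusters_selected: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        chain = (self.input_pairs, self.post_trim, self.merged)
        if not all(a >= b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"stage chain not non-increasing: {chain}")
        total_assigned = sum(self.assigned.values())
        if total_assigned + self.unassigned != self.merged:
            raise ValueError("assigned + unassigned != merged")
        for g in self.assigned:
            if self.assigned[g] < self.stripped[g]:
                raise ValueError(f"{g}: stripped exceeds assigned")
            if self.translated[g] != self.stripped[g]:
                raise ValueError(f"{g}: translated != stripped")
            if self.stop_removed[g] + self.retained[g] != self.translated[g]:
                raise ValueError(f"{g}: stop_removed + retained != translated")
            if self.clusters[g] > self.retained[g]:
                raise ValueError(f"{g}: more clusters than retained records")
            if self.clusters_selected[g] > self.clusters[g]:
                raise ValueError(f"{g}: selected exceeds clusters")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genotype": "__all__",
                "input_pairs": self.input_pairs,
                "post_trim": self.post_trim,
                "merged": self.merged,
                "assigned": sum(self.assigned.values()),
                "stripped": sum(self.stripped.values()),
                "translated": sum(self.translated.values()),
                "stop_removed": sum(self.stop_removed.values()),
                "retained": sum(self.retained.values()),
                "clusters": sum(self.clusters.values()),
                "clusters_selected": sum(self.clusters_selected.values()),
            }
        ]
        for g in sorted(self.assigned):
            rows.append(
                {
                    "genotype": g,
                    "input_pairs": pd.NA,
                    "post_trim": pd.NA,
                    "merged": pd.NA,
                    "assigned": self.assigned[g],
                    "stripped": self.stripped[g],
                    "translated": self.translated[g],
                    "stop_removed": self.stop_removed[g],
                    "retained": self.retained[g],
                    "clusters": self.clusters[g],
                    "clusters_selected": self.clusters_selected[g],
                }
            )
        return pd.DataFrame(rows).set_index("genotype")


@dataclass
class RunResult:
    counts: StageCounts
    frequency: FrequencyMatrix
    toxicity: pd.DataFrame
    newick: str | None
    out_dir: Path
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the report bundle into ``config.out_dir``."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gliascan")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: RunConfig, out: Path) -> RunResult:
    sheet = load_sample_sheet(config.sample_sheet)
    panel = load_panel(config.panel) if config.panel else packaged_panel()
    counts = StageCounts()
    records: list[ProteinRecord] = []
    merged_per_genotype: Counter = Counter()

    for pair in read_pairs(config.fwd_fastq, config.rev_fastq):
        counts.input_pairs += 1
        tf = quality_trim(
            pair.fwd_seq, pair.fwd_qual, config.window_size, config.mean_q, config.min_len
        )
        tr = quality_trim(
            pair.rev_seq, pair.rev_qual, config.window_size, config.mean_q, config.min_len
        )
        if tf is None or tr is None:
            continue
        counts.post_trim += 1
        pair.fwd_seq, pair.fwd_qual = tf
        pair.rev_seq, pair.rev_qual = tr
        amplicon = merge_pair(pair, config.min_overlap, config.max_mismatch_density)
        if amplicon is None:
            continue
        counts.merged += 1
        genotype = demultiplex(amplicon, sheet)
        if genotype == UNASSIGNED:
            counts.unassigned += 1
            continue
        counts.assigned[genotype] += 1
        merged_per_genotype[genotype] += 1
        cds = strip_technical(
            amplicon, signal_peptide_codons=config.signal_peptide_codons
        )
        if cds is None:
            continue
        counts.stripped[genotype] += 1
        protein = translate_cds(cds.cds)
        counts.translated[genotype] += 1
        records.append(ProteinRecord(id=cds.id, genotype=genotype, protein=protein))

    if counts.merged and counts.unassigned / counts.merged > 0.10:
        logger.warning(
            "unassigned fraction %.1f%% exceeds 10%%",
            100 * counts.unassigned / counts.merged,
        )

    retained, removed = filter_stops(records)
    for g, n in removed.items():
        counts.stop_removed[g] = n
    for rec in retained:
        counts.retained[rec.genotype] += 1

    clusters = cluster_identical(retained)
    for g, cl in clusters.items():
        counts.clusters[g] = len(cl)
    selected, _ = filter_clusters(clusters, config.min_members)
    for g, cl in selected.items():
        counts.clusters_selected[g] = len(cl)
    counts.validate()

    if config.depth_denominator == "retained":
        depth = {g: counts.retained[g] for g in selected}
    else:
        depth = {g: merged_per_genotype[g] for g in selected}
    usable = {g: cl for g, cl in selected.items() if depth.get(g, 0) > 0}
    dropped = sorted(set(selected) - set(usable))
    if dropped:
        logger.warning("genotype(s) with zero depth dropped from matrix: %s", dropped)
    if not usable:
        raise RuntimeError("no genotype with retained coding sequences")

    freq = FrequencyMatrix.from_clusters(
        usable, panel, {g: depth[g] for g in usable}, scale=config.scale
    )
    reports = toxicity_reports(freq, panel, use=config.toxicity_input)
    tox_table = toxicity_table(reports)

    consensi = genotype_consensi(usable, k=config.k_top)
    newick = None
    if len(consensi) >= 2:
        names = [g for g, _ in consensi]
        aln = align_center_star([c for _, c in consensi], names=names)
        dm = p_distance_matrix(aln)
        tree, _ = bootstrap_support(aln, n_reps=config.n_reps, seed=config.seed)
        newick = write_newick(tree)
        write_fasta(list(zip(aln.names, aln.rows)), out / "alignment.fasta")
        lower = pd.DataFrame(dm.d, index=dm.names, columns=dm.names)
        lower.where(
            pd.DataFrame(
                [[i > j for j in range(len(dm.names))] for i in range(len(dm.names))],
                index=dm.names,
                columns=dm.names,
            )
        ).to_csv(out / "distances.tsv", sep="\t", float_format="%.6f")
        (out / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
    else:
        logger.warning("fewer than 2 genotypes with consensi; tree skipped")
    write_fasta(consensi, out / "consensus.fasta")

    counts.to_frame().to_csv(out / "counts.tsv", sep="\t")
    freq.raw.to_csv(out / "frequency_raw.tsv", sep="\t")
    freq.normalized.to_csv(out / "frequency_normalized.tsv", sep="\t", float_format="%.6f")
    freq.log2().to_csv(out / "frequency_log2.tsv", sep="\t", float_format="%.6f")
    freq.presence_absence().to_csv(out / "presence_absence.tsv", sep="\t")
    tox_table.to_csv(out / "toxicity.tsv", sep="\t", float_format="%.6f")
    write_representatives_fasta(usable, out / "representatives.fasta")

    manifest = {
        "tool": "gliascan",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return RunResult(
        counts=counts,
        frequency=freq,
        toxicity=tox_table,
        newick=newick,
        out_dir=out,
        manifest=manifest,
    )


def simulate_command(
    out_dir: str | Path,
    n_genotypes: int = 10,
    depth: int = 20000,
    error_rate: float = 0.001,
    pseudogene_fraction: float = 0.3,
    seed: int = 0,
    layout: str = "pooled",
    panel: EpitopePanel | None = None,
) -> dict[str, Path]:
    """Write a synthetic dataset: FASTQ pair(s), truth table, sample sheet."""
    if layout not in ("pooled", "per-genotype"):
        raise ConfigError("layout must be 'pooled' or 'per-genotype'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = packaged_panel()
    specs = default_genotype_specs(
        depth=depth, pseudogene_fraction=pseudogene_fraction, n_genotypes=n_genotypes
    )
    config = SimulationConfig(seed=seed, substitution_error_rate=error_rate)
    paths: dict[str, Path] = {}
    if layout == "pooled":
        fwd, rev, truths = simulate_dataset(specs, config, panel)
        paths["fwd"] = out / "reads_R1.fastq"
        paths["rev"] = out / "reads_R2.fastq"
        write_fastq(fwd, paths["fwd"])
        write_fastq(rev, paths["rev"])
    else:
        import numpy as np

        rng = np.random.default_rng(seed)
        truths = []
        from .simulate import simulate_reads

        for spec in specs:
            f, r, t = simulate_reads(spec, config, panel, rng=rng)
            tag = spec.barcode
            paths[f"fwd_{tag}"] = out / f"{tag}_R1.fastq"
            paths[f"rev_{tag}"] = out / f"{tag}_R2.fastq"
            write_fastq(f, paths[f"fwd_{tag}"])
            write_fastq(r, paths[f"rev_{tag}"])
            truths.append(t)
    paths["truth"] = out / "truth.tsv"
    write_truth_table(truths, paths["truth"])
    paths["sample_sheet"] = out / "sample_sheet.tsv"
    write_sample_sheet([(s.name, s.barcode) for s in specs], paths["sample_sheet"])
    return paths
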