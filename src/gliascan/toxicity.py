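"""Toxicity-weighted immunogenicity load per genotype.

Each epitope's depth-normalised frequency is multiplied by its class weight
(HT/T: 3, MT/RT: 2, LT: 1; NT and unknown-class epitopes weigh 0) and the
products summed into a per-genotype load.  The genotype with the highest
load defines 100%; every other genotype is expressed relative to it.
Per-weight-group subtotals (HT/T, MT/RT, LT) are carried along so either
reading of "highest frequency for all groups" can be inspected.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .panel import TOXICITY_GROUPS, EpitopePanel, toxicity_weight
from .quantify import FrequencyMatrix

logger = logging.getLogger(__name__)

GROUPS = ("HT/T", "MT/RT", "LT")


@dataclass
class ToxicityReport:
    genotype: str
    weighted_load: float
    relative_percent: float
    group_sums: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weighted_load < 0:
            raise ValueError("negative weighted load")
        if not 0 <= self.relative_percent <= 100:
            raise ValueError("relative percent outside [0, 100]")


def toxicity_load(
    normalized_row: Mapping[str, float], panel: EpitopePanel
) -> tuple[float, dict[str, float]]:
    """Weighted load of one genotype: sum of weight(class) * frequency.

    Also returns the load partitioned into the HT/T, MT/RT and LT groups.
    Epitopes absent from ``normalized_row`` contribute nothing.
    """
    group_sums = {g: 0.0 for g in GROUPS}
    load = 0.0
    for e in panel:
        freq = float(normalized_row.get(e.id, 0.0))
        w = toxicity_weight(e.toxicity_class)
        if w == 0 or freq == 0.0:
            continue
        contrib = w * freq
        load += contrib
        group_sums[TOXICITY_GROUPS[e.toxicity_class]] += contrib
    return load, group_sums


def relative_toxicity(loads: Mapping[str, float]) -> dict[str, float]:
    """Percent of the maximal load per genotype (max genotype = 100).

    All-zero loads yield all-zero percentages with a warning.
    """
    if not loads:
        raise ValueError("no genotypes")
    top = max(loads.values())
    if top == 0:
        logger.warning("all toxicity loads are zero; relative percentages undefined")
        return {g: 0.0 for g in loads}
    return {g: 100.0 * load / top for g, load in loads.items()}


def rank_genotypes(reports: Sequence[ToxicityReport]) -> list[ToxicityReport]:
    """Descending by relative percent; ties broken alphabetically by name."""
    return sorted(reports, key=lambda r: (-r.relative_percent, r.genotype))


def toxicity_reports(
    freq: FrequencyMatrix, panel: EpitopePanel, use: str = "normalized"
) -> list[ToxicityReport]:
    """Toxicity reports for every genotype of a frequency matrix, ranked.

    ``use`` selects the score multiplicand: the depth-normalised frequencies
    (default) or the raw counts.
    """
    if use not in ("normalized", "raw"):
        raise ValueError("use must be 'normalized' or 'raw'")
    table = freq.normalized if use == "normalized" else freq.raw
    loads: dict[str, float] = {}
    groups: dict[str, dict[str, float]] = {}
    for g in freq.genotypes:
        loads[g], groups[g] = toxicity_load(table.loc[g].to_dict(), panel)
    percents = relative_toxicity(loads)
    reports = [
        ToxicityReport(
            genotype=g,
            weighted_load=loads[g],
            relative_percent=percents[g],
            group_sums=groups[g],
        )
        for g in freq.genotypes
    ]
    return rank_genotypes(reports)


def packaged_toxicity_fixture() -> pd.DataFrame:
    """Synthetic normalized-frequency fixture (genotypes x epitope ids) with
    hand-computable weighted loads, shipped for offline verification of the
    scoring arithmetic."""
    ref = importlib.resources.files("gliascan.data") / "synthetic_toxicity_fixture.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def toxicity_table(reports: Sequence[ToxicityReport]) -> pd.DataFrame:
    """Tabular report: group subtotals, load, relative percent, rank."""
    rows = []
    for rank, r in enumerate(rank_genotypes(list(reports)), start=1):
        rows.append(
            {
                "genotype": r.genotype,
                **{f"sum_{g.replace('/', '_')}": r.group_sums.get(g, 0.0) for g in GROUPS},
                "weighted_load": r.weighted_load,
                "relative_percent": round(r.relative_percent, 1),
                "rank": rank,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
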