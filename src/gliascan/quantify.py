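"""Epitope quantification: overlap-inclusive scanning of cluster
representatives, cluster-size weighting, depth normalisation, and the
genotype x epitope frequency matrix.

Counting is overlap-inclusive: every start position at which the epitope
matches is counted, which is what lets the 33-mer region carry six copies
of the DQ2.5-glia-alpha1/alpha2 epitopes.  Raw counts are weighted by
cluster size and normalised per ``scale`` (default 10,000) retained CDSs
per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ProteinCluster
from .panel import EpitopePanel


def count_occurrences(protein: str, epitope_sequence: str) -> int:
    """Number of (possibly overlapping) exact occurrences of the epitope."""
    if not epitope_sequence:
        raise ValueError("empty epitope sequence")
    if not protein or len(epitope_sequence) > len(protein):
        return 0
    count = 0
    start = protein.find(epitope_sequence)
    while start != -1:
        count += 1
        start = protein.find(epitope_sequence, start + 1)
    return count


def quantify(
    selected_clusters: Sequence[ProteinCluster], panel: EpitopePanel
) -> dict[str, int]:
    """Raw epitope counts for one genotype's selected clusters.

    ``raw[e] = sum over clusters of occurrences(representative, e) * size``.
    """
    raw = {e.id: 0 for e in panel}
    for cluster in selected_clusters:
        for e in panel:
            n = count_occurrences(cluster.representative, e.sequence)
            if n:
                raw[e.id] += n * cluster.size
    return raw


def normalize(
    raw_row: Mapping[str, int] | Sequence[float], depth: int, scale: float = 10000
) -> dict[str, float] | np.ndarray:
    """Depth-normalised frequencies: ``raw * scale / depth``."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if isinstance(raw_row, Mapping):
        return {k: v * scale / depth for k, v in raw_row.items()}
    return np.asarray(raw_row, dtype=float) * scale / depth


def log2_matrix(normalized: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise ``log2(value + 1)``; negative input is an error."""
    values = normalized.to_numpy() if isinstance(normalized, pd.DataFrame) else np.asarray(normalized, dtype=float)
    if (values < 0).any():
        raise ValueError("negative value in frequency matrix")
    out = np.log2(values + 1.0)
    if isinstance(normalized, pd.DataFrame):
        return pd.DataFrame(out, index=normalized.index, columns=normalized.columns)
    return out


@dataclass
class FrequencyMatrix:
    """Genotypes x epitopes table of raw and depth-normalised counts.

    ``depth`` is the per-genotype denominator (by default the retained,
    stop-free CDS count; optionally the merged-read count).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    depth: pd.Series

    def __post_init__(self) -> None:
        if not self.raw.index.equals(self.normalized.index) or not self.raw.columns.equals(
            self.normalized.columns
        ):
            raise ValueError("raw/normalized dimension mismatch")
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("negative raw count")

    @property
    def genotypes(self) -> list[str]:
        return list(self.raw.index)

    @property
    def epitope_ids(self) -> list[str]:
        return list(self.raw.columns)

    @classmethod
    def from_clusters(
        cls,
        selected_clusters: Mapping[str, Sequence[ProteinCluster]],
        panel: EpitopePanel,
        depth: Mapping[str, int],
        scale: float = 10000,
    ) -> "FrequencyMatrix":
        genotypes = sorted(selected_clusters)
        ids = list(panel.ids)
        raw = pd.DataFrame(0, index=genotypes, columns=ids, dtype=int)
        for g in genotypes:
            row = quantify(selected_clusters[g], panel)
            raw.loc[g] = [row[i] for i in ids]
        depth_s = pd.Series({g: depth[g] for g in genotypes}, dtype=int)
        if (depth_s <= 0).any():
            bad = list(depth_s.index[depth_s <= 0])
            raise ValueError(f"non-positive depth for genotype(s) {bad}")
        normalized = raw.div(depth_s, axis=0) * scale
        return cls(raw=raw, normalized=normalized, depth=depth_s)

    def log2(self) -> pd.DataFrame:
        return log2_matrix(self.normalized)

    def presence_absence(self) -> pd.DataFrame:
        """0/1 matrix: 1 iff the raw count is positive."""
        return (self.raw > 0).astype(int)

    def detected_per_genotype(self) -> pd.Series:
        """Number of distinct epitopes detected in each genotype."""
        return self.presence_absence().sum(axis=1)


def presence_absence(matrix: FrequencyMatrix, genotype: str) -> np.ndarray:
    """0/1 vector over the panel for one genotype (1 iff raw count > 0)."""
    return matrix.presence_absence().loc[genotype].to_numpy()
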