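"""Celiac-disease epitope panel: definitions, TSV I/O, toxicity weighting.

An epitope here is a short immunogenic peptide (canonical core of nine
residues for the HLA-DQ2.5-presented gliadin epitopes, longer for the
innate p31-43 family) with a toxicity class assigned from published in
vitro / clinical rankings.  Classes map to integer weights used by the
per-genotype toxicity load: highly toxic / toxic (HT, T) -> 3, moderately
toxic / reduced toxicity (MT, RT) -> 2, low toxicity (LT) -> 1.  Non-toxic
(NT) and unknown (unk) epitopes carry weight 0 and do not contribute.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

FAMILIES = ("alpha1", "alpha2", "alpha3", "p31-43", "other")
TOXICITY_CLASSES = ("HT", "T", "MT", "RT", "LT", "NT", "unk")

_WEIGHTS = {"HT": 3, "T": 3, "MT": 2, "RT": 2, "LT": 1, "NT": 0, "unk": 0}

#: Weight-class grouping used for per-genotype subtotals.
TOXICITY_GROUPS = {"HT": "HT/T", "T": "HT/T", "MT": "MT/RT", "RT": "MT/RT", "LT": "LT"}

PANEL_COLUMNS = ("id", "name", "sequence", "family", "toxicity_class", "mismatches")


class PanelError(ValueError):
    """Malformed or inconsistent epitope panel."""


def toxicity_weight(toxicity_class: str) -> int:
    """Integer toxicity weight of a class label (HT/T=3, MT/RT=2, LT=1, NT/unk=0)."""
    try:
        return _WEIGHTS[toxicity_class]
    except KeyError:
        raise PanelError(f"unknown toxicity class: {toxicity_class!r}") from None


@dataclass(frozen=True)
class Epitope:
    """A named immunogenic peptide with a toxicity class.

    ``mismatches_from_canonical`` is 0 for canonical entries and counts the
    residue substitutions separating a variant from its canonical form.
    """

    id: str
    name: str
    sequence: str
    family: str
    toxicity_class: str
    mismatches_from_canonical: int = 0

    def __post_init__(self) -> None:
        if not self.id or not self.id.isascii():
            raise PanelError(f"epitope id must be non-empty ASCII: {self.id!r}")
        if len(self.sequence) < 5:
            raise PanelError(f"epitope {self.id}: sequence shorter than 5 residues")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise PanelError(
                f"epitope {self.id}: illegal amino-acid letter(s) {sorted(bad)!r} "
                f"in {self.sequence!r}"
            )
        if self.family not in FAMILIES:
            raise PanelError(f"epitope {self.id}: unknown family {self.family!r}")
        if self.toxicity_class not in TOXICITY_CLASSES:
            raise PanelError(
                f"epitope {self.id}: unknown toxicity class {self.toxicity_class!r}"
            )
        if self.mismatches_from_canonical < 0:
            raise PanelError(f"epitope {self.id}: negative mismatch count")

    @property
    def weight(self) -> int:
        return toxicity_weight(self.toxicity_class)


@dataclass(frozen=True)
class EpitopePanel:
    """Ordered, validated collection of epitopes.

    ``placeholder_names`` records epitopes that belong in the panel by name
    but whose sequence must be supplied by a panel file (e.g. p31-43, whose
    sequence is not part of the built-in canonical set).
    """

    epitopes: tuple[Epitope, ...]
    source: str = "unspecified"
    placeholder_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.epitopes:
            raise PanelError("empty panel")
        ids = [e.id for e in self.epitopes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate epitope id(s): {dup}")
        pairs = [(e.name, e.sequence) for e in self.epitopes]
        if len(set(pairs)) != len(pairs):
            raise PanelError("duplicate (name, sequence) pair in panel")

    def __len__(self) -> int:
        return len(self.epitopes)

    def __iter__(self):
        return iter(self.epitopes)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.epitopes)

    def by_id(self, epitope_id: str) -> Epitope:
        for e in self.epitopes:
            if e.id == epitope_id:
                return e
        raise KeyError(epitope_id)


def load_panel(path: str | Path) -> EpitopePanel:
    """Load a TSV epitope panel.

    Expected header columns: ``id name sequence family toxicity_class
    mismatches`` (tab-separated); ``#`` lines are comments.  Raises
    :class:`PanelError` naming the offending line on malformed rows.
    """
    path = Path(path)
    epitopes: list[Epitope] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in PANEL_COLUMNS if c not in header]
                if missing:
                    raise PanelError(
                        f"{path}:{lineno}: missing column(s) {missing}"
                    )
                continue
            if len(fields) != len(header):
                raise PanelError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, (f.strip() for f in fields)))
            try:
                epitopes.append(
                    Epitope(
                        id=row["id"],
                        name=row["name"],
                        sequence=row["sequence"].upper(),
                        family=row["family"],
                        toxicity_class=row["toxicity_class"],
                        mismatches_from_canonical=int(row["mismatches"]),
                    )
                )
            except (PanelError, ValueError) as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from None
    if not epitopes:
        raise PanelError(f"{path}: empty panel")
    return EpitopePanel(tuple(epitopes), source=str(path))


def write_panel(panel: EpitopePanel, path: str | Path) -> None:
    """Write a panel as TSV, field-for-field round-trippable by load_panel."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for e in panel:
            fh.write(
                "\t".join(
                    (
                        e.id,
                        e.name,
                        e.sequence,
                        e.family,
                        e.toxicity_class,
                        str(e.mismatches_from_canonical),
                    )
                )
                + "\n"
            )


#: Canonical alpha-gliadin epitope sequences reported in the main analysis.
_CANONICAL = (
    Epitope("a1a", "DQ2.5-glia-α1a", "PFPQPQLPY", "alpha1", "HT", 0),
    Epitope("a1b", "DQ2.5-glia-α1b", "PYPQPQLPY", "alpha1", "HT", 0),
    Epitope("a2", "DQ2.5-glia-α2", "PQPQLPYPQ", "alpha2", "HT", 0),
    Epitope("a3", "DQ2.5-glia-α3", "FRPQQPYPQ", "alpha3", "MT", 0),
    Epitope("ave1b", "DQ2.5-ave-1b", "PYPEQEQPF", "other", "unk", 0),
    Epitope("g1", "DQ2.5-glia-g1", "PQQSFPEQQ", "other", "unk", 0),
)


def builtin_canonical_panel() -> EpitopePanel:
    """The six canonical epitopes whose sequences are fixed by the assay.

    p31-43 is listed as a placeholder name only: its sequence is not part of
    this built-in set and must be supplied by a panel file.
    """
    return EpitopePanel(
        _CANONICAL, source="builtin canonical", placeholder_names=("p31-43",)
    )


def packaged_panel() -> EpitopePanel:
    """The synthetic stand-in panel shipped with the package.

    Canonical sequences are the published ones; variant sequences and their
    toxicity classes are constructed (synthetic) so the full pipeline —
    variant scanning, class weighting, grouping — is exercisable offline.
    """
    ref = importlib.resources.files("gliascan.data") / "synthetic_epitope_panel.tsv"
    with importlib.resources.as_file(ref) as path:
        panel = load_panel(path)
    return EpitopePanel(
        panel.epitopes, source="packaged synthetic stand-in panel"
    )
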