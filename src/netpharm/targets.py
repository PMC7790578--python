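"""Compound-target maps and the set algebra behind herb/disease Venn overlaps.

Targets are HGNC-style gene symbols, uppercased and whitespace-trimmed; no
alias resolution is attempted — two symbols are the same gene iff the
normalised strings are equal. The operations here answer the standard
questions of a herb-pair study: which genes does each herb hit, which genes
do the herbs share, and which drug targets are also disease genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .compounds import CompoundRecord
from .errors import ParseError

__all__ = [
    "TargetMap",
    "GeneSet",
    "OverlapReport",
    "read_target_map",
    "read_gene_list",
    "targets_of_herb",
    "set_intersection_report",
    "intersection_size_from_counts",
    "drug_disease_overlap",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped and uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class TargetMap:
    """Many-to-many compound -> gene-symbol relation.

    ``pairs`` holds de-duplicated ``(compound_id, gene_symbol)`` tuples with
    symbols already normalised.
    """

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TargetMap":
        return cls(
            frozenset((cid, normalize_symbol(sym)) for cid, sym in pairs)
        )

    def targets_of(self, compound_id: str) -> set[str]:
        return {sym for cid, sym in self.pairs if cid == compound_id}

    def compounds_with_targets(self) -> set[str]:
        return {cid for cid, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of normalised gene symbols."""

    label: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(normalize_symbol(g) for g in genes if g.strip()))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column TSV of (compound_id, gene_symbol) pairs.

    Symbols are normalised and duplicate pairs collapse under set
    semantics. Raises :class:`ParseError` with the line number on a
    malformed row.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}: line {line_no}: expected two tab-separated "
                    f"fields, got {line!r}"
                )
            pairs.add((parts[0].strip(), normalize_symbol(parts[1])))
    return TargetMap(frozenset(pairs))


def read_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a gene list, one symbol per line; ``#`` comments allowed."""
    path = Path(path)
    genes = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if text:
                genes.append(text)
    return GeneSet.from_iterable(label or path.stem, genes)


def targets_of_herb(
    target_map: TargetMap, compounds: Iterable[CompoundRecord], label: str | None = None
) -> GeneSet:
    """Union of gene targets over a herb's compounds.

    Compounds absent from the map contribute nothing. The label defaults
    to the herb of the first compound.
    """
    compounds = list(compounds)
    ids = {c.compound_id for c in compounds}
    genes = {sym for cid, sym in target_map.pairs if cid in ids}
    if label is None:
        label = compounds[0].herb if compounds else "herb"
    return GeneSet(label, frozenset(genes))


@dataclass(frozen=True)
class OverlapReport:
    """Sizes and membership of a two-set comparison (one Venn panel)."""

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    n_intersection: int
    n_union: int
    intersection: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        # inclusion-exclusion must hold for any pair of finite sets
        if self.size_a + self.size_b != self.n_union + self.n_intersection:
            raise ValueError(
                "inclusion-exclusion violated: "
                f"{self.size_a}+{self.size_b} != {self.n_union}+{self.n_intersection}"
            )


def set_intersection_report(a: GeneSet, b: GeneSet) -> OverlapReport:
    """Compare two gene sets, returning sizes and the sorted intersection."""
    inter = a.genes & b.genes
    union = a.genes | b.genes
    return OverlapReport(
        label_a=a.label,
        label_b=b.label,
        size_a=len(a.genes),
        size_b=len(b.genes),
        n_intersection=len(inter),
        n_union=len(union),
        intersection=tuple(sorted(inter)),
    )


def intersection_size_from_counts(size_a: int, size_b: int, size_union: int) -> int:
    """Intersection size implied by |A|, |B| and |A ∪ B| (inclusion-exclusion).

    Raises ``ValueError`` if the three counts are not realisable by any
    pair of finite sets.
    """
    inter = size_a + size_b - size_union
    if inter < 0 or inter > min(size_a, size_b) or size_union < max(size_a, size_b):
        raise ValueError(
            f"no sets realise |A|={size_a}, |B|={size_b}, |A∪B|={size_union}"
        )
    return inter


def drug_disease_overlap(drug: GeneSet, disease: GeneSet) -> GeneSet:
    """Genes shared by the drug target set and the disease gene set."""
    return GeneSet("overlap", drug.genes & disease.genes)
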