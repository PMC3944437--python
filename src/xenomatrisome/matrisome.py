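"""Matrisome annotation and the two-replicate membership rule.

The matrisome — the ensemble of extracellular-matrix and ECM-associated
proteins — is divided into the *core matrisome* (ECM glycoproteins,
collagens, proteoglycans) and *matrisome-associated* proteins (ECM-affiliated
proteins, ECM regulators, secreted factors).  Annotation is keyed on gene
symbol, case-insensitively, so that the human and mouse forms of one protein
collapse to a single biological entity.

A protein belongs to a tumor's matrisome when it is detected in both
biological replicates and by at least two peptides in one of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

CORE_MATRISOME = "core_matrisome"
MATRISOME_ASSOCIATED = "matrisome_associated"
NON_MATRISOME = "non_matrisome"

CORE_CATEGORIES = frozenset({"ECM_glycoproteins", "collagens", "proteoglycans"})
ASSOCIATED_CATEGORIES = frozenset(
    {"ECM_affiliated", "ECM_regulators", "secreted_factors"}
)
CATEGORIES = CORE_CATEGORIES | ASSOCIATED_CATEGORIES | {"none"}


class AnnotationError(ValueError):
    """Malformed annotation table or inconsistent division/category pair."""


@dataclass(frozen=True)
class MatrisomeAnnotation:
    gene_symbol: str
    division: str
    category: str

    def __post_init__(self) -> None:
        if self.division == CORE_MATRISOME and self.category not in CORE_CATEGORIES:
            raise AnnotationError(
                f"{self.gene_symbol}: core matrisome requires a core category, "
                f"got {self.category!r}"
            )
        if (
            self.division == MATRISOME_ASSOCIATED
            and self.category not in ASSOCIATED_CATEGORIES
        ):
            raise AnnotationError(
                f"{self.gene_symbol}: matrisome-associated requires an associated "
                f"category, got {self.category!r}"
            )
        if self.division == NON_MATRISOME and self.category != "none":
            raise AnnotationError(
                f"{self.gene_symbol}: non-matrisome entries carry category 'none'"
            )
        if self.division not in (CORE_MATRISOME, MATRISOME_ASSOCIATED, NON_MATRISOME):
            raise AnnotationError(f"{self.gene_symbol}: unknown division {self.division!r}")

    @property
    def is_matrisome(self) -> bool:
        return self.division != NON_MATRISOME


_NON = MatrisomeAnnotation("", NON_MATRISOME, "none")


class AnnotationTable:
    """Case-insensitive gene-symbol lookup; unknown genes are non-matrisome."""

    def __init__(self, annotations: Mapping[str, MatrisomeAnnotation]):
        self._by_gene = {g.upper(): a for g, a in annotations.items()}

    def get(self, gene_symbol: str) -> MatrisomeAnnotation:
        return self._by_gene.get(gene_symbol.upper(), _NON)

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol.upper() in self._by_gene

    def __len__(self) -> int:
        return len(self._by_gene)


def load_annotation(path: str | Path) -> AnnotationTable:
    """Read a tab-separated annotation table with gene, division, category.

    Raises :class:`AnnotationError` on malformed rows or an inconsistent
    division/category pair.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_symbol", "division", "category"}
    if not required <= set(df.columns):
        raise AnnotationError(
            f"annotation table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    table: dict[str, MatrisomeAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = MatrisomeAnnotation(str(row.gene_symbol), str(row.division), str(row.category))
        table[ann.gene_symbol] = ann
    return AnnotationTable(table)


def write_annotation(path: str | Path, annotations: Sequence[MatrisomeAnnotation]) -> None:
    pd.DataFrame(
        [
            {"gene_symbol": a.gene_symbol, "division": a.division, "category": a.category}
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def matrisome_membership(per_replicate_peptide_counts: Sequence[int]) -> bool:
    """Detected in both replicates, with at least two peptides in one of them.

    Exactly two counts are expected (one per biological replicate); the rule
    is symmetric and monotone in both counts.
    """
    counts = list(per_replicate_peptide_counts)
    if len(counts) != 2:
        raise ValueError(f"expected exactly two replicate counts, got {len(counts)}")
    return min(counts) >= 1 and max(counts) >= 2
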