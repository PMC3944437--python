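"""Per-tumor matrisome signatures and their comparison.

A tumor's matrisome is the set of matrisome-annotated proteins that pass the
two-replicate membership rule.  Comparing two tumor types yields the Venn
partition (shared / A-only / B-only) and, over the shared proteins with a
determinate origin in both types, the split between proteins secreted by the
same compartment in both tumors and those whose tumor/stroma origin shifts
with metastatic potential.

Origin shifts are compared on the coarse three-class scale (tumor / stroma /
both) by default; the exact six-class comparison is available via
``coarse=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .matrisome import AnnotationTable, matrisome_membership
from .quantify import COARSE_CLASS, UNDETERMINED, OriginCall, classify_origin


class SignatureError(ValueError):
    """Violated signature invariant or inconsistent comparison input."""


@dataclass(frozen=True)
class MatrisomeProtein:
    """One matrisome member of one tumor type, with its evidence counts."""

    gene_symbol: str
    division: str
    category: str
    peptide_counts: tuple[int, int]  # distinct peptides per replicate


@dataclass
class SignatureResult:
    """Comparison of two tumor-type matrisomes.

    ``origin_same`` and ``origin_shifted`` partition the shared genes with a
    determinate origin in both types; shared genes that are undetermined on
    either side fall into ``origin_indeterminate``.
    """

    type_a: str
    type_b: str
    matrisome_a: dict[str, MatrisomeProtein]
    matrisome_b: dict[str, MatrisomeProtein]
    origin_calls_a: dict[str, OriginCall] = field(default_factory=dict)
    origin_calls_b: dict[str, OriginCall] = field(default_factory=dict)
    origin_same: set[str] = field(default_factory=set)
    origin_shifted: set[str] = field(default_factory=set)
    origin_indeterminate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        a, b = set(self.matrisome_a), set(self.matrisome_b)
        shared, only_a, only_b = a & b, a - b, b - a
        if shared | only_a | only_b != a | b:
            raise SignatureError("Venn parts must partition the union")
        if len(shared) + len(only_a) != len(a) or len(shared) + len(only_b) != len(b):
            raise SignatureError("Venn counts inconsistent with set sizes")
        if self.origin_same & self.origin_shifted:
            raise SignatureError("origin_same and origin_shifted must be disjoint")
        if not (self.origin_same | self.origin_shifted) <= shared:
            raise SignatureError("origin classes must be subsets of the shared genes")

    @property
    def shared(self) -> set[str]:
        return set(self.matrisome_a) & set(self.matrisome_b)

    @property
    def a_only(self) -> set[str]:
        return set(self.matrisome_a) - set(self.matrisome_b)

    @property
    def b_only(self) -> set[str]:
        return set(self.matrisome_b) - set(self.matrisome_a)

    @property
    def venn_counts(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.a_only), len(self.b_only))

    def summary(self) -> dict:
        return {
            "tumor_types": [self.type_a, self.type_b],
            "matrisome_sizes": {
                self.type_a: len(self.matrisome_a),
                self.type_b: len(self.matrisome_b),
            },
            "venn": {
                "shared": len(self.shared),
                f"{self.type_a}_only": len(self.a_only),
                f"{self.type_b}_only": len(self.b_only),
            },
            "origin": {
                "same": len(self.origin_same),
                "shifted": len(self.origin_shifted),
                "indeterminate": len(self.origin_indeterminate),
            },
        }


def build_matrisome(
    per_replicate_counts: Mapping[str, tuple[int, int]],
    annotation: AnnotationTable,
) -> dict[str, MatrisomeProtein]:
    """Apply the membership rule per gene and keep matrisome-annotated genes.

    ``per_replicate_counts`` maps gene symbol to its distinct-peptide counts
    in the two biological replicates of one tumor type.
    """
    out: dict[str, MatrisomeProtein] = {}
    for gene, counts in per_replicate_counts.items():
        if not matrisome_membership(counts):
            continue
        ann = annotation.get(gene)
        if not ann.is_matrisome:
            continue
        key = gene.upper()
        out[key] = MatrisomeProtein(
            gene_symbol=key,
            division=ann.division,
            category=ann.category,
            peptide_counts=(int(counts[0]), int(counts[1])),
        )
    return out


def compare_matrisomes(
    set_a: Mapping[str, MatrisomeProtein],
    set_b: Mapping[str, MatrisomeProtein],
    type_a: str = "A",
    type_b: str = "B",
) -> SignatureResult:
    """Venn comparison of two per-type matrisomes keyed on gene symbol."""
    return SignatureResult(
        type_a=type_a,
        type_b=type_b,
        matrisome_a=dict(set_a),
        matrisome_b=dict(set_b),
    )


def detect_origin_shifts(
    shared_genes: set[str],
    origin_calls_a: Mapping[str, OriginCall],
    origin_calls_b: Mapping[str, OriginCall],
    coarse: bool = True,
) -> tuple[set[str], set[str], set[str]]:
    """Split shared genes into (same, shifted, indeterminate) origin sets.

    A gene is shifted iff both calls are determinate and differ as classes;
    an undetermined call on either side makes it indeterminate.  With
    ``coarse=True`` the six classes collapse to tumor / stroma / both first.
    """
    same: set[str] = set()
    shifted: set[str] = set()
    indeterminate: set[str] = set()
    for gene in shared_genes:
        call_a = origin_calls_a.get(gene)
        call_b = origin_calls_b.get(gene)
        cls_a = call_a.origin_class if call_a else UNDETERMINED
        cls_b = call_b.origin_class if call_b else UNDETERMINED
        if coarse:
            cls_a, cls_b = COARSE_CLASS[cls_a], COARSE_CLASS[cls_b]
        if UNDETERMINED in (cls_a, cls_b):
            indeterminate.add(gene)
        elif cls_a == cls_b:
            same.add(gene)
        else:
            shifted.add(gene)
    return same, shifted, indeterminate


def matrisome_table(matrisome: Mapping[str, MatrisomeProtein]) -> pd.DataFrame:
    rows = [
        {
            "gene_symbol": p.gene_symbol,
            "division": p.division,
            "category": p.category,
            "peptides_rep1": p.peptide_counts[0],
            "peptides_rep2": p.peptide_counts[1],
        }
        for p in matrisome.values()
    ]
    return (
        pd.DataFrame(rows).sort_values("gene_symbol").reset_index(drop=True)
        if rows
        else pd.DataFrame(
            columns=["gene_symbol", "division", "category", "peptides_rep1", "peptides_rep2"]
        )
    )


# ---------------------------------------------------------------------------
# reproduction of published summary counts from deposited tables


def reproduce_published_counts(
    membership_table: str | Path,
    origin_table_path: str | Path,
    fold_threshold: float = 5.0,
) -> dict[str, int]:
    """Re-derive summary counts from normalized deposited data tables.

    ``membership_table`` is a TSV with columns ``gene_symbol``,
    ``typeA_rep1``, ``typeA_rep2``, ``typeB_rep1``, ``typeB_rep2`` holding
    distinct-peptide counts per biological replicate (prepared from the
    deposited per-protein MS tables).  ``origin_table_path`` is a TSV with
    ``gene_symbol``, ``tumor_type``, ``human_intensity``, ``mouse_intensity``
    (summed species-specific precursor intensities; NA when no species-
    specific peptides were observed).

    Applies the two-replicate membership rule, the Venn comparison, and the
    fivefold origin rule with coarse-class shift detection, returning the
    counts that summarize the comparison.
    """
    mem = pd.read_csv(membership_table, sep="\t")
    sets: dict[str, set[str]] = {}
    for t in ("A", "B"):
        keep = mem.apply(
            lambda r: matrisome_membership(
                (int(r[f"type{t}_rep1"]), int(r[f"type{t}_rep2"]))
            ),
            axis=1,
        )
        sets[t] = set(mem.loc[keep, "gene_symbol"].str.upper())
    shared = sets["A"] & sets["B"]

    orig = pd.read_csv(origin_table_path, sep="\t")
    calls: dict[str, dict[str, OriginCall]] = {"A": {}, "B": {}}
    for row in orig.itertuples(index=False):
        gene = str(row.gene_symbol).upper()
        h = float(row.human_intensity) if pd.notna(row.human_intensity) else 0.0
        m = float(row.mouse_intensity) if pd.notna(row.mouse_intensity) else 0.0
        has_evidence = h > 0 or m > 0
        calls[str(row.tumor_type)][gene] = OriginCall(
            gene, h, m, classify_origin(h, m, fold_threshold, has_evidence)
        )
    same, shifted, indeterminate = detect_origin_shifts(
        shared, calls["A"], calls["B"], coarse=True
    )
    return {
        "matrisome_size_A": len(sets["A"]),
        "matrisome_size_B": len(sets["B"]),
        "venn_shared": len(shared),
        "venn_A_only": len(sets["A"] - sets["B"]),
        "venn_B_only": len(sets["B"] - sets["A"]),
        "origin_same": len(same),
        "origin_shifted": len(shifted),
        "origin_indeterminate": len(indeterminate),
    }
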