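"""Label-free quantification and tumor vs stroma origin calls.

A protein's abundance on each side of the species divide is the summed
precursor ion current (XIC) of its quantifiable species-specific peptide
ions.  Peptides shared across subgroups of a group, and precursors with a
poorly defined isotope cluster, are not quantifiable.  A protein is
*quantifiable* when it appears in both independent samples with at least two
distinct peptides in one of them.

The origin call applies a conservative fivefold dominance rule to the
human/mouse intensity ratio: only human signal -> tumor only; only mouse ->
stroma only; both, with one side at least five times the other -> dominant;
both within fivefold -> similar; no species-specific signal at all -> the
origin cannot be determined ("?").  No normalization is applied between
human and mouse ionization efficiencies; ratios are generally reliable only
to within about twofold, which is why the threshold is conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .inference import ProteinSubgroup
from .proteomes import HUMAN_SPECIFIC, MOUSE_SPECIFIC

DEFAULT_FOLD_THRESHOLD = 5.0

TUMOR_ONLY = "tumor_only"
STROMA_ONLY = "stroma_only"
BOTH_SIMILAR = "both_similar"
BOTH_TUMOR_DOMINANT = "both_tumor_dominant"
BOTH_STROMA_DOMINANT = "both_stroma_dominant"
UNDETERMINED = "undetermined"

ORIGIN_CLASSES = (
    TUMOR_ONLY,
    STROMA_ONLY,
    BOTH_SIMILAR,
    BOTH_TUMOR_DOMINANT,
    BOTH_STROMA_DOMINANT,
    UNDETERMINED,
)

#: coarse three-class view: which compartment secretes the protein at all
COARSE_CLASS = {
    TUMOR_ONLY: "tumor",
    BOTH_TUMOR_DOMINANT: "both",
    BOTH_SIMILAR: "both",
    BOTH_STROMA_DOMINANT: "both",
    STROMA_ONLY: "stroma",
    UNDETERMINED: UNDETERMINED,
}


@dataclass(frozen=True)
class OriginCall:
    """Per-protein species-resolved intensities and origin class."""

    gene_symbol: str
    human_intensity: float
    mouse_intensity: float
    origin_class: str

    @property
    def ratio(self) -> float:
        """Human/mouse intensity ratio; inf or nan at the boundaries."""
        if self.mouse_intensity > 0:
            return self.human_intensity / self.mouse_intensity
        return math.inf if self.human_intensity > 0 else math.nan


def quantifiable_peptides(subgroup: ProteinSubgroup) -> frozenset[str]:
    """Peptides usable for quantification: unique to this subgroup in its group."""
    return subgroup.specific_peptides


def quantifiable_psms(
    psms: pd.DataFrame, subgroup: ProteinSubgroup
) -> pd.DataFrame:
    """PSMs of the subgroup's quantifiable peptides with good isotope quality."""
    peps = quantifiable_peptides(subgroup)
    mask = psms["peptide"].isin(peps) & psms["good_isotope_quality"]
    return psms[mask]


def _ion_intensities(psms: pd.DataFrame) -> pd.Series:
    # one XIC per precursor ion per run: collapse repeated spectra of the same
    # (sample, fraction, peptide, modification variant, charge) to one value,
    # then sum ions across fractions and samples
    keys = ["sample_id", "fraction_id", "peptide", "modifications", "charge"]
    return psms.groupby(keys, sort=False)["precursor_intensity"].max()


def protein_abundance(
    subgroup: ProteinSubgroup,
    psms: pd.DataFrame,
    species: str,
    species_labels: Mapping[str, str],
) -> float:
    """Summed ion current of the subgroup's species-specific quantifiable ions.

    ``species`` is ``"human"`` or ``"mouse"``; peptides whose label is shared
    between species contribute to neither side.
    """
    label = {"human": HUMAN_SPECIFIC, "mouse": MOUSE_SPECIFIC}[species]
    q = quantifiable_psms(psms, subgroup)
    q = q[q["peptide"].map(lambda p: species_labels.get(p)) == label]
    if q.empty:
        return 0.0
    return float(_ion_intensities(q).sum())


def protein_quantifiable(per_sample_distinct_peptide_counts: Sequence[int]) -> bool:
    """Represented in two independent samples, >= 2 distinct peptides in one."""
    counts = list(per_sample_distinct_peptide_counts)
    if len(counts) != 2:
        raise ValueError(f"expected exactly two sample counts, got {len(counts)}")
    return min(counts) >= 1 and max(counts) >= 2


def classify_origin(
    human_intensity: float,
    mouse_intensity: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    has_species_specific_evidence: bool = True,
) -> str:
    """Fivefold dominance rule on summed species-specific intensities.

    A ratio exactly at the threshold counts as dominant ("at least five
    times").  Without any species-specific evidence the origin is
    undetermined.  The call is invariant to rescaling both intensities and
    mirror-symmetric under swapping the species.
    """
    if human_intensity < 0 or mouse_intensity < 0:
        raise ValueError("intensities must be nonnegative")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if not has_species_specific_evidence or (
        human_intensity == 0 and mouse_intensity == 0
    ):
        return UNDETERMINED
    if mouse_intensity == 0:
        return TUMOR_ONLY
    if human_intensity == 0:
        return STROMA_ONLY
    # product comparisons keep the tumor<->stroma mirror exact in floats
    if human_intensity >= fold_threshold * mouse_intensity:
        return BOTH_TUMOR_DOMINANT
    if mouse_intensity >= fold_threshold * human_intensity:
        return BOTH_STROMA_DOMINANT
    return BOTH_SIMILAR


def gene_origin_calls(
    subgroups: Iterable[ProteinSubgroup],
    psms: pd.DataFrame,
    species_labels: Mapping[str, str],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> dict[str, OriginCall]:
    """One origin call per gene, pooling replicates and subgroups.

    The human and mouse subgroups of one ortholog pair carry the same gene
    symbol (case-insensitive, human symbol canonical); their species-specific
    quantifiable ion currents are summed per side before the fivefold rule is
    applied.  ``psms`` should hold the retained PSMs of one tumor type (both
    replicates pooled).
    """
    human_by_gene: dict[str, float] = {}
    mouse_by_gene: dict[str, float] = {}
    evidence: dict[str, bool] = {}
    for sg in subgroups:
        gene = sg.gene_symbol.upper()
        h = protein_abundance(sg, psms, "human", species_labels)
        m = protein_abundance(sg, psms, "mouse", species_labels)
        human_by_gene[gene] = human_by_gene.get(gene, 0.0) + h
        mouse_by_gene[gene] = mouse_by_gene.get(gene, 0.0) + m
        has_specific = any(
            species_labels.get(p) in (HUMAN_SPECIFIC, MOUSE_SPECIFIC)
            for p in quantifiable_peptides(sg)
        )
        evidence[gene] = evidence.get(gene, False) or has_specific
    calls = {}
    for gene in human_by_gene:
        calls[gene] = OriginCall(
            gene_symbol=gene,
            human_intensity=human_by_gene[gene],
            mouse_intensity=mouse_by_gene[gene],
            origin_class=classify_origin(
                human_by_gene[gene],
                mouse_by_gene[gene],
                fold_threshold,
                evidence[gene],
            ),
        )
    return calls


def origin_table(calls: Mapping[str, OriginCall], tumor_type: str) -> pd.DataFrame:
    rows = [
        {
            "gene_symbol": c.gene_symbol,
            "tumor_type": tumor_type,
            "human_intensity": c.human_intensity,
            "mouse_intensity": c.mouse_intensity,
            "ratio": c.ratio,
            "origin_class": c.origin_class,
            "origin_coarse": COARSE_CLASS[c.origin_class],
        }
        for c in calls.values()
    ]
    return pd.DataFrame(rows).sort_values("gene_symbol").reset_index(drop=True)
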