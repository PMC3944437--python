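"""Sequence databases, in silico tryptic digestion, and species-specific peptides.

A human tumor grown in a mouse host deposits an extracellular matrix built by
two genomes at once: human sequences mark tumor-cell products, mouse sequences
mark host (stromal) products.  Attribution therefore runs through tryptic
peptides: a peptide whose sequence occurs in only one species' database is
*species-specific* and anchors the protein to that compartment, while peptides
conserved between the orthologs are *shared* and uninformative for origin.

This module reads the paired FASTA databases, digests them with trypsin rules
(cleavage C-terminal to K or R, suppressed before proline, with a configurable
number of missed cleavages), and classifies peptide sequences as
human-specific, mouse-specific, or shared.  Because mass spectrometry cannot
distinguish leucine from isoleucine, specificity calls are made after mapping
residues through configurable equivalence classes (I≡L by default).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

HUMAN = "human"
MOUSE = "mouse"

HUMAN_SPECIFIC = "human_specific"
MOUSE_SPECIFIC = "mouse_specific"
SHARED = "shared"

#: the 20 standard residues plus X for positions of unknown identity
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: residues equated when deciding species specificity; I/L are isobaric and
#: indistinguishable by MS.  N/D merging (deamidation ambiguity) is available
#: but off by default.
DEFAULT_EQUIVALENCE: tuple[frozenset[str], ...] = (frozenset("IL"),)

_CLEAVAGE_RE = re.compile(r"(?<=[KR])(?!P)")


class ProteomeError(ValueError):
    """Malformed or inconsistent sequence-database input."""


@dataclass(frozen=True)
class ProteomeEntry:
    """One sequence-database record.

    ``is_decoy`` marks reversed-sequence entries used for target-decoy FDR
    estimation; (accession, is_decoy) is unique within a database.
    """

    accession: str
    species: str
    gene_symbol: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteomeError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ProteomeError(
                f"{self.accession}: invalid residues {sorted(bad)!r}"
            )
        if self.species not in (HUMAN, MOUSE):
            raise ProteomeError(f"{self.accession}: unknown species {self.species!r}")


@dataclass(frozen=True)
class PeptideRecord:
    """A tryptic peptide with its parents and species-specificity label."""

    sequence: str
    parent_accessions: frozenset[str]
    missed_cleavages: int
    species_label: str


def _gene_from_description(description: str, accession: str) -> str:
    m = re.search(r"GN=(\S+)", description)
    return m.group(1) if m else accession


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path, species: str) -> list[ProteomeEntry]:
    """Read one species' database; gene symbols are taken from ``GN=`` tags.

    Raises :class:`ProteomeError` on an empty file or duplicate accession.
    """
    entries: list[ProteomeEntry] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            accession = rec.id
            if accession in seen:
                raise ProteomeError(f"duplicate accession {accession!r} in {path}")
            seen.add(accession)
            entries.append(
                ProteomeEntry(
                    accession=accession,
                    species=species,
                    gene_symbol=_gene_from_description(rec.description, accession),
                    sequence=str(rec.seq).upper(),
                )
            )
    if not entries:
        raise ProteomeError(f"no FASTA records in {path}")
    return entries


def read_proteomes(
    path_human: str | Path, path_mouse: str | Path
) -> tuple[list[ProteomeEntry], list[ProteomeEntry]]:
    """Read the paired human and mouse databases."""
    return read_fasta(path_human, HUMAN), read_fasta(path_mouse, MOUSE)


def reverse_decoy(entry: ProteomeEntry) -> ProteomeEntry:
    """Reversed-sequence decoy counterpart of a target entry."""
    return ProteomeEntry(
        accession=f"rev_{entry.accession}",
        species=entry.species,
        gene_symbol=f"rev_{entry.gene_symbol}",
        sequence=entry.sequence[::-1],
        is_decoy=True,
    )


def with_decoys(entries: Iterable[ProteomeEntry]) -> list[ProteomeEntry]:
    """Targets plus one reversed decoy per target."""
    out: list[ProteomeEntry] = []
    for e in entries:
        out.append(e)
        out.append(reverse_decoy(e))
    return out


def cleavage_fragments(sequence: str) -> list[str]:
    """Ordered 0-missed-cleavage products: split after K/R unless before P.

    Concatenating the result reproduces ``sequence`` exactly.
    """
    if not sequence:
        raise ProteomeError("cannot digest an empty sequence")
    return [f for f in _CLEAVAGE_RE.split(sequence) if f]


def digest(
    sequence: str,
    max_missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 50,
) -> list[tuple[str, int]]:
    """Tryptic peptides of ``sequence`` as (peptide, missed_cleavages) pairs.

    Every peptide with m missed cleavages is the concatenation of m+1
    consecutive fully-cleaved fragments; only peptides whose length falls in
    [min_length, max_length] are returned.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    frags = cleavage_fragments(sequence)
    out: list[tuple[str, int]] = []
    for i in range(len(frags)):
        pep = ""
        for m in range(max_missed_cleavages + 1):
            if i + m >= len(frags):
                break
            pep += frags[i + m]
            if min_length <= len(pep) <= max_length:
                out.append((pep, m))
    return out


def equivalence_table(
    classes: Sequence[frozenset[str]] = DEFAULT_EQUIVALENCE,
) -> dict[int, int]:
    """str.translate table collapsing each residue class to one representative."""
    table: dict[int, int] = {}
    for cls in classes:
        rep = min(cls)
        for residue in cls:
            table[ord(residue)] = ord(rep)
    return table


def apply_equivalence(
    sequence: str, classes: Sequence[frozenset[str]] = DEFAULT_EQUIVALENCE
) -> str:
    """Map a peptide through the residue-equivalence classes (e.g. I -> L rep)."""
    return sequence.translate(equivalence_table(classes))


@dataclass
class DigestIndex:
    """Peptide -> parent-accession lookup for one species' digested database.

    Keys are equivalence-mapped sequences; ``records`` retains the literal
    peptides for serialization.
    """

    species: str
    equivalence: tuple[frozenset[str], ...] = DEFAULT_EQUIVALENCE
    peptides: dict[str, set[str]] = field(default_factory=dict)
    missed: dict[str, int] = field(default_factory=dict)

    def __contains__(self, mapped_peptide: str) -> bool:
        return mapped_peptide in self.peptides

    def parents(self, peptide: str) -> frozenset[str]:
        mapped = apply_equivalence(peptide, self.equivalence)
        return frozenset(self.peptides.get(mapped, ()))


def build_digest_index(
    entries: Iterable[ProteomeEntry],
    species: str,
    max_missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 50,
    equivalence: Sequence[frozenset[str]] = DEFAULT_EQUIVALENCE,
) -> DigestIndex:
    """Digest every entry and index peptides by equivalence-mapped sequence."""
    index = DigestIndex(species=species, equivalence=tuple(equivalence))
    table = equivalence_table(equivalence)
    for entry in entries:
        for pep, mc in digest(entry.sequence, max_missed_cleavages, min_length, max_length):
            mapped = pep.translate(table)
            index.peptides.setdefault(mapped, set()).add(entry.accession)
            prev = index.missed.get(mapped)
            if prev is None or mc < prev:
                index.missed[mapped] = mc
    return index


def classify_species_specificity(
    peptide_sequence: str,
    human_index: DigestIndex,
    mouse_index: DigestIndex,
    equivalence: Sequence[frozenset[str]] = DEFAULT_EQUIVALENCE,
) -> str:
    """Label a peptide human_specific / mouse_specific / shared.

    A peptide is *shared* when its equivalence-mapped sequence occurs in the
    digests of both species.  A peptide absent from both indices signals a
    PSM/database mismatch and raises ``KeyError``.
    """
    mapped = apply_equivalence(peptide_sequence, equivalence)
    in_human = mapped in human_index
    in_mouse = mapped in mouse_index
    if in_human and in_mouse:
        return SHARED
    if in_human:
        return HUMAN_SPECIFIC
    if in_mouse:
        return MOUSE_SPECIFIC
    raise KeyError(
        f"peptide {peptide_sequence!r} not found in either species' digest"
    )


def peptide_records(
    human_index: DigestIndex, mouse_index: DigestIndex
) -> Iterator[PeptideRecord]:
    """All indexed peptides with parents from both species and their labels."""
    for mapped in sorted(set(human_index.peptides) | set(mouse_index.peptides)):
        in_h = mapped in human_index
        in_m = mapped in mouse_index
        label = SHARED if (in_h and in_m) else (HUMAN_SPECIFIC if in_h else MOUSE_SPECIFIC)
        parents = frozenset(human_index.peptides.get(mapped, set())) | frozenset(
            mouse_index.peptides.get(mapped, set())
        )
        mc = min(
            x
            for x in (human_index.missed.get(mapped), mouse_index.missed.get(mapped))
            if x is not None
        )
        yield PeptideRecord(mapped, parents, mc, label)


def write_digest_index(
    path: str | Path, human_index: DigestIndex, mouse_index: DigestIndex
) -> None:
    """Serialize the combined index as TSV: peptide, label, parents, missed."""
    with open(path, "w") as fh:
        fh.write("peptide\tspecies_label\tparent_accessions\tmissed_cleavages\n")
        for rec in peptide_records(human_index, mouse_index):
            fh.write(
                f"{rec.sequence}\t{rec.species_label}\t"
                f"{';'.join(sorted(rec.parent_accessions))}\t{rec.missed_cleavages}\n"
            )


def write_fasta(path: str | Path, entries: Iterable[ProteomeEntry]) -> None:
    """Write entries as FASTA with gene symbols in ``GN=`` tags."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.accession} GN={e.gene_symbol}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")
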