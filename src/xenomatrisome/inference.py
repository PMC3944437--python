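"""Protein inference: distinct peptides, shared-peptide grouping, subgroups.

MS/MS identifications arrive as redundant peptide-spectrum matches; protein
reporting collapses them in three steps:

1. *Distinct peptides*: every PSM with the same bare peptide sequence —
   regardless of charge state, fraction, or modification variant — collapses
   to a single entry holding the highest score.
2. *Groups*: database entries that share a detected peptide longer than eight
   residues are joined into one group (connected components of the
   protein-peptide graph).  This absorbs isoforms, close paralogs, and
   cross-species orthologs into a single reporting unit.
3. *Subgroups*: within a group, any member carrying at least one distinct
   peptide found in no other member spawns its own subgroup (this is how the
   human and mouse orthologs of one protein become, e.g., 25.1 and 25.2);
   members without unique evidence join the best-scoring compatible subgroup.

A subgroup's protein score is the sum of the best scores of its distinct
peptides; reported proteins must reach a minimum score (20 by default) and
survive a protein-level FDR of zero against reversed-sequence decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteomes import (
    HUMAN_SPECIFIC,
    MOUSE_SPECIFIC,
    SHARED,
    ProteomeEntry,
)

DEFAULT_GROUPING_MIN_LENGTH = 8  # peptides strictly longer than this group proteins
DEFAULT_MIN_PROTEIN_SCORE = 20.0


class InferenceError(ValueError):
    """Inconsistent inference input (e.g. a peptide with no database parent)."""


@dataclass
class DistinctPeptide:
    """Best-scoring instance of a peptide sequence across all its PSMs."""

    sequence: str
    best_score: float
    psm_rows: list[int] = field(default_factory=list)
    best_row: int = -1


def distinct_peptides(psms: pd.DataFrame) -> dict[str, DistinctPeptide]:
    """Collapse FDR-filtered PSMs to one entry per bare peptide sequence.

    Charge states, fractions, and modification variants of one sequence all
    contribute to a single distinct peptide carrying the maximum score.
    """
    out: dict[str, DistinctPeptide] = {}
    for row, pep, score in psms[["peptide", "score"]].itertuples():
        entry = out.get(pep)
        if entry is None:
            out[pep] = DistinctPeptide(pep, float(score), [row], row)
        else:
            entry.psm_rows.append(row)
            if score > entry.best_score:
                entry.best_score = float(score)
                entry.best_row = row


    return out


@dataclass
class ProteinSubgroup:
    """One reported protein: a subgroup of a shared-peptide group.

    ``distinct_peptides`` maps each contributing peptide sequence to its best
    score; ``specific_peptides`` are those unique to this subgroup within its
    group (the quantifiable ones).  Rendered identifier is ``"G.S"``.
    """

    group_number: int
    subgroup_index: int
    member_accessions: frozenset[str]
    representative_accession: str
    distinct_peptides: dict[str, float]
    protein_score: float
    species_content: str  # human / mouse / mixed
    gene_symbol: str
    is_decoy: bool
    specific_peptides: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        return f"{self.group_number}.{self.subgroup_index}"


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def group_proteins(
    distinct_peptide_map: Mapping[str, DistinctPeptide],
    protein_databases: Mapping[str, ProteomeEntry],
    peptide_parents: Mapping[str, frozenset[str]],
    grouping_min_length: int = DEFAULT_GROUPING_MIN_LENGTH,
) -> list[ProteinSubgroup]:
    """Group entries sharing detected peptides > ``grouping_min_length`` residues.

    ``peptide_parents`` maps each detected peptide to its database entries
    (from the digest index, residue-equivalence applied).  Every distinct
    peptide must have at least one parent, otherwise :class:`InferenceError`.

    Within each connected component, members with unique peptide evidence
    spawn subgroups ordered by descending subgroup score (index from 1);
    members without unique evidence join the highest-scoring subgroup whose
    peptide set covers theirs.  Groups are numbered by descending total group
    score, ties broken by representative accession.
    """
    uf = _UnionFind()
    pep_parent_sets: dict[str, frozenset[str]] = {}
    for pep in distinct_peptide_map:
        parents = peptide_parents.get(pep, frozenset())
        if not parents:
            raise InferenceError(f"peptide {pep!r} matches no database entry")
        unknown = [a for a in parents if a not in protein_databases]
        if unknown:
            raise InferenceError(f"peptide {pep!r} has unknown parents {unknown}")
        pep_parent_sets[pep] = parents
        for acc in parents:
            uf.find(acc)
        if len(pep) > grouping_min_length:
            first = next(iter(parents))
            for acc in parents:
                uf.union(first, acc)

    # provisional peptide -> group assignment (a peptide counts toward one group)
    group_weight: dict[str, float] = {}
    for pep, dp in distinct_peptide_map.items():
        for root in {uf.find(a) for a in pep_parent_sets[pep]}:
            group_weight[root] = group_weight.get(root, 0.0) + dp.best_score
    # a peptide short enough to escape the grouping rule can match entries in
    # several groups; it counts toward exactly one — the heaviest group,
    # ties broken by lexicographically smallest root
    pep_group: dict[str, str] = {}
    for pep in distinct_peptide_map:
        roots = {uf.find(a) for a in pep_parent_sets[pep]}
        pep_group[pep] = min(
            roots, key=lambda r: (-group_weight.get(r, 0.0), r)
        )

    members_by_group: dict[str, set[str]] = {}
    for pep, parents in pep_parent_sets.items():
        root = pep_group[pep]
        for acc in parents:
            if uf.find(acc) == root:
                members_by_group.setdefault(root, set()).add(acc)

    subgroups: list[ProteinSubgroup] = []
    group_records: list[tuple[float, str, list[ProteinSubgroup]]] = []
    for root, members in members_by_group.items():
        group_peps = [p for p in pep_group if pep_group[p] == root]
        member_peps: dict[str, set[str]] = {m: set() for m in members}
        for pep in group_peps:
            for acc in pep_parent_sets[pep] & members:
                member_peps[acc].add(pep)
        member_score = {
            m: sum(distinct_peptide_map[p].best_score for p in peps)
            for m, peps in member_peps.items()
        }

        unique_evidence = {
            m: {
                p
                for p in member_peps[m]
                if len(pep_parent_sets[p] & members) == 1
            }
            for m in members
        }
        spawners = sorted(
            (m for m in members if unique_evidence[m]),
            key=lambda m: (-member_score[m], m),
        )
        if not spawners:
            # no member has unique evidence: single subgroup, best member leads
            spawners = [min(members, key=lambda m: (-member_score[m], m))]

        sub_members: dict[str, set[str]] = {s: {s} for s in spawners}
        for m in sorted(members):
            if m in sub_members:
                continue
            compatible = [
                s for s in spawners if member_peps[m] <= member_peps[s]
            ]
            pool = compatible if compatible else spawners
            best = min(pool, key=lambda s: (-member_score[s], s))
            sub_members[best].add(m)

        group_subs: list[ProteinSubgroup] = []
        for s in spawners:
            mem = frozenset(sub_members[s])
            peps = set().union(*(member_peps[m] for m in mem))
            other_peps = set()
            for s2 in spawners:
                if s2 != s:
                    other_peps |= set().union(
                        *(member_peps[m] for m in sub_members[s2])
                    )
            specific = frozenset(p for p in peps if p not in other_peps)
            score = sum(distinct_peptide_map[p].best_score for p in peps)
            species = {protein_databases[m].species for m in mem}
            rep = min(mem, key=lambda m: (-member_score[m], m))
            group_subs.append(
                ProteinSubgroup(
                    group_number=0,
                    subgroup_index=0,
                    member_accessions=mem,
                    representative_accession=rep,
                    distinct_peptides={
                        p: distinct_peptide_map[p].best_score for p in sorted(peps)
                    },
                    protein_score=score,
                    species_content=species.pop() if len(species) == 1 else "mixed",
                    gene_symbol=protein_databases[rep].gene_symbol,
                    is_decoy=all(protein_databases[m].is_decoy for m in mem),
                    specific_peptides=specific,
                )
            )
        group_subs.sort(key=lambda sg: (-sg.protein_score, sg.representative_accession))
        for i, sg in enumerate(group_subs, start=1):
            sg.subgroup_index = i
        total = sum(distinct_peptide_map[p].best_score for p in group_peps)
        group_records.append((total, group_subs[0].representative_accession, group_subs))

    group_records.sort(key=lambda rec: (-rec[0], rec[1]))
    for number, (_, _, subs) in enumerate(group_records, start=1):
        for sg in subs:
            sg.group_number = number
        subgroups.extend(subs)
    return subgroups


def protein_score(
    subgroup: ProteinSubgroup, subgroup_specific_mode: bool = False
) -> float:
    """Sum of best distinct-peptide scores; optionally subgroup-specific only."""
    if subgroup_specific_mode:
        return sum(
            s
            for p, s in subgroup.distinct_peptides.items()
            if p in subgroup.specific_peptides
        )
    return sum(subgroup.distinct_peptides.values())


def protein_level_filter(
    subgroups: Sequence[ProteinSubgroup],
    min_protein_score: float = DEFAULT_MIN_PROTEIN_SCORE,
    max_protein_fdr: float = 0.0,
) -> list[ProteinSubgroup]:
    """Score filter plus a protein-level FDR of zero against decoy subgroups.

    Subgroups below ``min_protein_score`` are dropped; if any decoy subgroup
    survives the score cut, the effective cutoff rises just above the highest
    surviving decoy score so that no decoy is reported (protein FDR 0).  A
    nonzero ``max_protein_fdr`` keeps the plain ratio rule instead.
    """
    scored = [sg for sg in subgroups if sg.protein_score >= min_protein_score]
    decoy_scores = sorted(
        (sg.protein_score for sg in scored if sg.is_decoy), reverse=True
    )
    if not decoy_scores:
        return [sg for sg in scored if not sg.is_decoy]
    if max_protein_fdr == 0.0:
        cutoff = decoy_scores[0]
        return [
            sg for sg in scored if not sg.is_decoy and sg.protein_score > cutoff
        ]
    targets = sorted(
        (sg.protein_score for sg in scored if not sg.is_decoy), reverse=True
    )
    # smallest cutoff with decoys/targets above it within the budget
    for cut in sorted({sg.protein_score for sg in scored}):
        n_t = sum(1 for s in targets if s >= cut)
        n_d = sum(1 for s in decoy_scores if s >= cut)
        if n_t and n_d / n_t <= max_protein_fdr:
            return [
                sg
                for sg in scored
                if not sg.is_decoy and sg.protein_score >= cut
            ]
    return []


def peptide_counts(
    subgroup: ProteinSubgroup,
    species_labels: Mapping[str, str],
    mode: str = "total",
) -> int:
    """Count distinct peptides as total / species_specific / common.

    ``species_labels`` maps peptide sequence to human_specific /
    mouse_specific / shared; total = human-specific + mouse-specific + common.
    """
    labels = [species_labels[p] for p in subgroup.distinct_peptides]
    if mode == "total":
        return len(labels)
    if mode == "common":
        return sum(1 for x in labels if x == SHARED)
    if mode == "species_specific":
        return sum(1 for x in labels if x in (HUMAN_SPECIFIC, MOUSE_SPECIFIC))
    if mode == "human_specific":
        return sum(1 for x in labels if x == HUMAN_SPECIFIC)
    if mode == "mouse_specific":
        return sum(1 for x in labels if x == MOUSE_SPECIFIC)
    raise ValueError(f"unknown peptide-count mode {mode!r}")


def subgroup_table(
    subgroups: Iterable[ProteinSubgroup], species_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Tabular report: one row per subgroup with scores and peptide counts."""
    rows = []
    for sg in subgroups:
        rows.append(
            {
                "subgroup": sg.label,
                "representative_accession": sg.representative_accession,
                "gene_symbol": sg.gene_symbol,
                "species": sg.species_content,
                "protein_score": sg.protein_score,
                "n_peptides_total": peptide_counts(sg, species_labels, "total"),
                "n_peptides_human_specific": peptide_counts(
                    sg, species_labels, "human_specific"
                ),
                "n_peptides_mouse_specific": peptide_counts(
                    sg, species_labels, "mouse_specific"
                ),
                "n_peptides_common": peptide_counts(sg, species_labels, "common"),
                "is_decoy": sg.is_decoy,
            }
        )
    return pd.DataFrame(rows)
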