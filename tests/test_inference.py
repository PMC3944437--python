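"""Distinct peptides, shared-peptide grouping, subgroups, and protein filters."""

import itertools

import numpy as np
import pytest

from conftest import make_psms
from xenomatrisome.inference import (
    InferenceError,
    distinct_peptides,
    group_proteins,
    peptide_counts,
    protein_level_filter,
    protein_score,
    subgroup_table,
)
from xenomatrisome.proteomes import ProteomeEntry


class TestDistinctPeptides:
    def test_charge_states_collapse_to_best_score(self):
        psms = make_psms(
            [
                {"peptide": "AAAWEEEK", "charge": 2, "score": 12},
                {"peptide": "AAAWEEEK", "charge": 3, "score": 15},
            ]
        )
        d = distinct_peptides(psms)
        assert set(d) == {"AAAWEEEK"}
        assert d["AAAWEEEK"].best_score == 15
        assert len(d["AAAWEEEK"].psm_rows) == 2

    def test_modified_and_unmodified_forms_collapse(self):
        psms = make_psms(
            [
                {"peptide": "MAAWEEEK", "score": 14},
                {"peptide": "MAAWEEEK", "modifications": "1:oxidation_M", "score": 10},
            ]
        )
        assert len(distinct_peptides(psms)) == 1

    def test_different_sequences_stay_separate(self):
        psms = make_psms(
            [{"peptide": "AAAWEEEK", "score": 12}, {"peptide": "CCCWEEEK", "score": 9}]
        )
        assert len(distinct_peptides(psms)) == 2


def _entries(*specs):
    """specs: (accession, species, gene, is_decoy) -> dummy-sequence entries."""
    return {
        acc: ProteomeEntry(acc, species, gene, "MKR", is_decoy=decoy)
        for acc, species, gene, decoy in specs
    }


def _dp(scores):
    psms = make_psms([{"peptide": p, "score": s} for p, s in scores.items()])
    return distinct_peptides(psms)


class TestGrouping:
    def test_shared_long_peptide_single_subgroup(self):
        # two entries share a 10-mer and have no unique evidence
        entries = _entries(("P1", "human", "G1", False), ("P2", "human", "G1B", False))
        dmap = _dp({"AAAAAAAAAK": 12.0})
        parents = {"AAAAAAAAAK": frozenset({"P1", "P2"})}
        subs = group_proteins(dmap, entries, parents)
        assert len(subs) == 1
        sg = subs[0]
        assert sg.member_accessions == {"P1", "P2"}
        assert sg.label == "1.1"
        assert sg.representative_accession == "P1"  # tie broken lexicographically

    def test_ortholog_pair_spawns_two_subgroups(self):
        # human and mouse orthologs share a 10-mer; each has one unique peptide
        entries = _entries(("HUM1", "human", "TNC", False), ("MOU1", "mouse", "Tnc", False))
        dmap = _dp({"AAAAAAAAAK": 10.0, "CCCCWEEEK": 12.0, "CCCCWEDEK": 11.0})
        parents = {
            "AAAAAAAAAK": frozenset({"HUM1", "MOU1"}),
            "CCCCWEEEK": frozenset({"HUM1"}),
            "CCCCWEDEK": frozenset({"MOU1"}),
        }
        subs = group_proteins(dmap, entries, parents)
        assert [sg.label for sg in subs] == ["1.1", "1.2"]
        assert {sg.representative_accession for sg in subs} == {"HUM1", "MOU1"}
        by_rep = {sg.representative_accession: sg for sg in subs}
        # shared peptide contributes to both subgroups' scores but is not specific
        assert by_rep["HUM1"].protein_score == 22.0
        assert by_rep["MOU1"].protein_score == 21.0
        assert by_rep["HUM1"].specific_peptides == {"CCCCWEEEK"}
        assert by_rep["HUM1"].subgroup_index == 1  # higher score ranks first

    def test_eight_mer_does_not_group(self):
        # the rule is strictly "> 8 residues"
        entries = _entries(("P1", "human", "G1", False), ("P2", "human", "G2", False))
        dmap = _dp({"AAAAAAAK": 10.0, "CCCCWEEEK": 5.0, "DDDDWEEEK": 6.0})
        parents = {
            "AAAAAAAK": frozenset({"P1", "P2"}),
            "CCCCWEEEK": frozenset({"P1"}),
            "DDDDWEEEK": frozenset({"P2"}),
        }
        subs = group_proteins(dmap, entries, parents)
        assert len({sg.group_number for sg in subs}) == 2
        nine = dict(parents)
        dmap9 = _dp({"AAAAAAAAK": 10.0, "CCCCWEEEK": 5.0, "DDDDWEEEK": 6.0})
        nine = {
            "AAAAAAAAK": frozenset({"P1", "P2"}),
            "CCCCWEEEK": frozenset({"P1"}),
            "DDDDWEEEK": frozenset({"P2"}),
        }
        subs9 = group_proteins(dmap9, entries, nine)
        assert len({sg.group_number for sg in subs9}) == 1

    def test_orphan_peptide_raises(self):
        entries = _entries(("P1", "human", "G1", False))
        dmap = _dp({"AAAAAAAAAK": 10.0})
        with pytest.raises(InferenceError):
            group_proteins(dmap, entries, {"AAAAAAAAAK": frozenset()})

    def test_groups_numbered_by_descending_score(self):
        entries = _entries(("P1", "human", "G1", False), ("P2", "human", "G2", False))
        dmap = _dp({"CCCCWEEEK": 5.0, "DDDDWEEEK": 20.0})
        parents = {
            "CCCCWEEEK": frozenset({"P1"}),
            "DDDDWEEEK": frozenset({"P2"}),
        }
        subs = group_proteins(dmap, entries, parents)
        best = min(subs, key=lambda s: s.group_number)
        assert best.representative_accession == "P2"


class TestGroupingOracle:
    """Randomized comparison against a brute-force enumeration."""

    @staticmethod
    def brute_force(peptide_parents, scores, min_len=8):
        accs = sorted(set().union(*peptide_parents.values()))
        long_peps = [p for p in peptide_parents if len(p) > min_len]
        adj = {a: set() for a in accs}
        for p in long_peps:
            for a, b in itertools.combinations(sorted(peptide_parents[p]), 2):
                adj[a].add(b)
                adj[b].add(a)
        seen, comps = set(), []
        for a in accs:
            if a in seen:
                continue
            stack, comp = [a], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        spawners = {}
        for comp in comps:
            sp = set()
            for m in comp:
                for p, parents in peptide_parents.items():
                    if parents & comp == {m}:
                        sp.add(m)
            spawners[comp] = frozenset(sp)
        return comps, spawners

    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(2024)
        aa = np.array(list("ACDEFGHKLMNQRSTVWY"))
        for trial in range(200):
            n_prot = int(rng.integers(2, 13))
            accs = [f"P{i:02d}" for i in range(n_prot)]
            n_pep = int(rng.integers(1, 20))
            peptide_parents, scores = {}, {}
            for _ in range(n_pep):
                length = int(rng.integers(9, 13))  # all peptides group-capable
                pep = "".join(rng.choice(aa, size=length))
                k = int(rng.integers(1, min(4, n_prot) + 1))
                peptide_parents[pep] = frozenset(
                    rng.choice(accs, size=k, replace=False)
                )
                scores[pep] = float(np.round(rng.uniform(1, 25), 2))
            entries = {
                a: ProteomeEntry(a, "human", f"G{a}", "MKR") for a in accs
            }
            dmap = _dp(scores)
            subs = group_proteins(dmap, entries, peptide_parents)

            comps, spawners = self.brute_force(peptide_parents, scores)
            detected_accs = set().union(*peptide_parents.values())
            got_groups = {}
            for sg in subs:
                got_groups.setdefault(sg.group_number, set()).update(
                    sg.member_accessions
                )
            exp_groups = {
                frozenset(c & detected_accs) for c in comps if c & detected_accs
            }
            assert {frozenset(g) for g in got_groups.values()} == exp_groups

            # spawned subgroups per component match the unique-evidence census
            for comp in comps:
                comp_subs = [
                    sg for sg in subs if sg.member_accessions <= comp
                ]
                if not comp_subs:
                    continue
                expected_spawners = spawners[comp]
                if expected_spawners:
                    reps = set()
                    for sg in comp_subs:
                        reps.update(
                            m
                            for m in sg.member_accessions
                            if any(
                                peptide_parents[p] & comp == {m}
                                for p in sg.distinct_peptides
                            )
                        )
                    assert reps == set(expected_spawners)
                    assert len(comp_subs) == len(expected_spawners)
                else:
                    assert len(comp_subs) == 1
                # indices consecutive from 1, ordered by descending score
                idx = sorted(sg.subgroup_index for sg in comp_subs)
                assert idx == list(range(1, len(comp_subs) + 1))
                ordered = sorted(comp_subs, key=lambda s: s.subgroup_index)
                assert all(
                    a.protein_score >= b.protein_score
                    for a, b in zip(ordered, ordered[1:])
                )

            # every distinct peptide is counted toward exactly one group
            pep_seen = {}
            for sg in subs:
                for p in sg.distinct_peptides:
                    pep_seen.setdefault(p, set()).add(sg.group_number)
            assert all(len(gs) == 1 for gs in pep_seen.values())
            assert set(pep_seen) == set(peptide_parents)


class TestScoringAndFilter:
    def _single_subgroup(self, scores, specific=None):
        entries = _entries(("P1", "human", "G1", False))
        dmap = _dp(scores)
        parents = {p: frozenset({"P1"}) for p in scores}
        (sg,) = group_proteins(dmap, entries, parents)
        return sg

    def test_protein_score_sums_distinct_peptides(self):
        sg = self._single_subgroup({"AAAAWEEEK": 10.0, "CCCCWEEEK": 12.0})
        assert protein_score(sg) == 22.0

    def test_single_excellent_peptide_passes_alone(self):
        sg = self._single_subgroup({"AAAAWEEEK": 25.0})
        assert protein_score(sg) == 25.0
        assert protein_level_filter([sg], min_protein_score=20.0) == [sg]

    def test_subgroup_specific_mode_zero_when_all_shared(self):
        entries = _entries(("P1", "human", "G1", False), ("P2", "human", "G2", False))
        dmap = _dp({"AAAAAAAAAK": 10.0, "CCCCWEEEK": 5.0, "DDDDWEEEK": 6.0})
        parents = {
            "AAAAAAAAAK": frozenset({"P1", "P2"}),
            "CCCCWEEEK": frozenset({"P1"}),
            "DDDDWEEEK": frozenset({"P2"}),
        }
        subs = group_proteins(dmap, entries, parents)
        for sg in subs:
            specific = protein_score(sg, subgroup_specific_mode=True)
            full = protein_score(sg)
            assert specific <= full
            shared_contrib = 10.0 if "AAAAAAAAAK" in sg.distinct_peptides else 0.0
            assert full - specific == shared_contrib

    def test_score_monotone_under_added_peptides(self):
        small = self._single_subgroup({"AAAAWEEEK": 10.0})
        big = self._single_subgroup({"AAAAWEEEK": 10.0, "CCCCWEEEK": 0.5})
        assert protein_score(big) >= protein_score(small)

    def test_filter_drops_below_minimum_score(self):
        a = self._single_subgroup({"AAAAWEEEK": 25.0})
        b = self._single_subgroup({"CCCCWEEEK": 19.0})
        assert protein_level_filter([a, b]) == [a]

    def test_protein_fdr_zero_raises_cutoff_above_decoys(self):
        entries = _entries(("P1", "human", "G1", False), ("rev_P1", "human", "rG1", True))
        dmap = _dp({"AAAAWEEEK": 22.0, "KEEEWAAAA": 23.0})
        parents = {
            "AAAAWEEEK": frozenset({"P1"}),
            "KEEEWAAAA": frozenset({"rev_P1"}),
        }
        subs = group_proteins(dmap, entries, parents)
        assert protein_level_filter(subs) == []

    def test_all_targets_retained_without_decoys(self):
        a = self._single_subgroup({"AAAAWEEEK": 21.0})
        b = self._single_subgroup({"CCCCWEEEK": 20.0})
        assert protein_level_filter([a, b]) == [a, b]


class TestPeptideCounts:
    def _subgroup(self):
        entries = _entries(("P1", "human", "G1", False))
        scores = {
            "AAAAWEEEK": 10.0,
            "CCCCWEEEK": 10.0,
            "DDDDWEEEK": 10.0,
            "EEEEWEEEK": 10.0,
            "FFFFWEEEK": 10.0,
        }
        dmap = _dp(scores)
        parents = {p: frozenset({"P1"}) for p in scores}
        (sg,) = group_proteins(dmap, entries, parents)
        labels = {
            "AAAAWEEEK": "human_specific",
            "CCCCWEEEK": "human_specific",
            "DDDDWEEEK": "human_specific",
            "EEEEWEEEK": "shared",
            "FFFFWEEEK": "shared",
        }
        return sg, labels

    def test_counts_by_mode_and_conservation(self):
        sg, labels = self._subgroup()
        total = peptide_counts(sg, labels, "total")
        common = peptide_counts(sg, labels, "common")
        specific = peptide_counts(sg, labels, "species_specific")
        assert (total, common, specific) == (5, 2, 3)
        assert total == specific + common
        assert peptide_counts(sg, labels, "mouse_specific") == 0

    def test_subgroup_table_columns(self):
        sg, labels = self._subgroup()
        table = subgroup_table([sg], labels)
        assert table.loc[0, "n_peptides_total"] == 5
        assert table.loc[0, "subgroup"] == "1.1"
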