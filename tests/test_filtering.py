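"""Spectral FDR thresholding and motif QC checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_psms
from xenomatrisome.filtering import (
    FilterError,
    compute_spectral_thresholds,
    filter_psms,
    filtering_report,
    flag_hydroxyproline_context,
    infer_deglycosylation_sites,
    read_psm_table,
    restrict_charges,
    spectral_fdr_threshold,
    validate_psm_table,
    write_psm_table,
)


def psms_from_scores(targets, decoys, charge=2):
    rows = [{"peptide": f"T{i}K", "score": s, "charge": charge} for i, s in enumerate(targets)]
    rows += [
        {"peptide": f"D{i}K", "score": s, "charge": charge, "is_decoy": True}
        for i, s in enumerate(decoys)
    ]
    return make_psms(rows)


def brute_force_threshold(targets, decoys, fdr):
    """Exhaustive scan over the observed score grid (independent oracle)."""
    grid = sorted(set(targets) | set(decoys))
    for t in grid:
        n_t = sum(1 for s in targets if s >= t)
        n_d = sum(1 for s in decoys if s >= t)
        if n_t and n_d / n_t <= fdr:
            return t
    return math.inf


class TestSpectralThreshold:
    def test_decoys_all_below_targets(self):
        psms = psms_from_scores([10, 12, 15], [5, 6])
        assert spectral_fdr_threshold(psms, 2, 0.0) == 10

    def test_worked_example_interleaved(self):
        # hand-derived with the exhaustive scan: t=15 is the smallest cutoff
        # with decoys/targets <= 0.30
        psms = psms_from_scores([10, 12, 15, 20], [11, 14])
        assert spectral_fdr_threshold(psms, 2, 0.30) == 15

    def test_zero_fdr_forces_above_max_decoy(self):
        psms = psms_from_scores([10, 12, 15, 20], [11, 14])
        t = spectral_fdr_threshold(psms, 2, 0.0)
        assert t == 15  # smallest observed score above every decoy

    def test_unreachable_target_returns_inf(self):
        psms = psms_from_scores([10], [12])
        assert spectral_fdr_threshold(psms, 2, 0.0) == math.inf

    def test_no_targets_raises(self):
        psms = psms_from_scores([], [5.0])
        with pytest.raises(FilterError):
            spectral_fdr_threshold(psms, 2, 0.1)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 25), min_size=1, max_size=30),
        st.lists(st.integers(0, 25), min_size=0, max_size=30),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_matches_brute_force_and_is_minimal(self, targets, decoys, fdr):
        psms = psms_from_scores(targets, decoys)
        t = spectral_fdr_threshold(psms, 2, fdr)
        assert t == brute_force_threshold(targets, decoys, fdr)
        if math.isfinite(t):
            for cand in sorted(set(targets) | set(decoys)):
                if cand >= t:
                    break
                n_t = sum(1 for s in targets if s >= cand)
                n_d = sum(1 for s in decoys if s >= cand)
                assert n_t == 0 or n_d / n_t > fdr

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 25), min_size=1, max_size=20),
        st.lists(st.integers(0, 25), min_size=0, max_size=20),
        st.floats(min_value=0.0, max_value=0.5),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_monotone_in_target_fdr(self, targets, decoys, fdr_lo, fdr_hi):
        if fdr_lo > fdr_hi:
            fdr_lo, fdr_hi = fdr_hi, fdr_lo
        psms = psms_from_scores(targets, decoys)
        assert spectral_fdr_threshold(psms, 2, fdr_lo) >= spectral_fdr_threshold(
            psms, 2, fdr_hi
        )


class TestFilterPsms:
    def test_zero_thresholds_keep_everything(self):
        psms = psms_from_scores([1, 2, 3], [0.5])
        thresholds = {("A_r1|f1", 2): 0.0}
        assert len(filter_psms(psms, thresholds)) == len(psms)

    def test_infinite_thresholds_drop_everything(self):
        psms = psms_from_scores([1, 2, 3], [])
        assert filter_psms(psms, {("A_r1|f1", 2): math.inf}).empty

    def test_mixed_charges_match_rowwise_evaluation(self):
        rows = [
            {"peptide": "AAAK", "charge": 2, "score": 10},
            {"peptide": "CCCK", "charge": 2, "score": 4},
            {"peptide": "DDDK", "charge": 3, "score": 8},
            {"peptide": "EEEK", "charge": 3, "score": 12},
        ]
        psms = make_psms(rows)
        thresholds = {("A_r1|f1", 2): 5.0, ("A_r1|f1", 3): 10.0}
        kept = filter_psms(psms, thresholds)
        # row-wise oracle
        expected = [r["peptide"] for r in rows if r["score"] >= thresholds[("A_r1|f1", r["charge"])]]
        assert list(kept["peptide"]) == expected

    def test_missing_threshold_raises(self):
        psms = psms_from_scores([5], [])
        with pytest.raises(FilterError):
            filter_psms(psms, {})

    def test_out_of_range_charges_dropped(self):
        psms = make_psms(
            [{"peptide": "AAAK", "charge": c} for c in (1, 2, 3, 4, 5)]
        )
        assert sorted(restrict_charges(psms)["charge"]) == [2, 3, 4]

    def test_per_run_thresholds_computed_separately(self):
        psms = pd.concat(
            [
                psms_from_scores([10, 20], [15]),
                psms_from_scores([22, 24], [2]).assign(sample_id="B_r1"),
            ],
            ignore_index=True,
        )
        thresholds = compute_spectral_thresholds(psms, target_fdr=0.0)
        assert thresholds[("A_r1|f1", 2)] == 20
        assert thresholds[("B_r1|f1", 2)] == 22
        report = filtering_report(psms, thresholds)
        assert set(report["run"]) == {"A_r1|f1", "B_r1|f1"}
        assert (report["achieved_fdr"] == 0).all()


class TestPsmTableIO:
    def test_round_trip(self, tmp_path):
        psms = make_psms(
            [{"peptide": "MAAAK", "modifications": "1:oxidation_M", "score": 11.5}]
        )
        write_psm_table(tmp_path / "p.tsv", psms)
        back = read_psm_table(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(back, psms)

    def test_score_range_enforced(self):
        with pytest.raises(FilterError):
            validate_psm_table(make_psms([{"peptide": "AAAK", "score": 26.0}]))

    def test_modification_residue_mismatch_rejected(self):
        bad = make_psms([{"peptide": "AAAK", "modifications": "2:oxidation_M"}])
        with pytest.raises(FilterError):
            validate_psm_table(bad)

    def test_modification_position_bounds(self):
        bad = make_psms([{"peptide": "MAAK", "modifications": "9:oxidation_M"}])
        with pytest.raises(FilterError):
            validate_psm_table(bad)


class TestMotifChecks:
    @pytest.mark.parametrize(
        "pep,pos,expected",
        [
            ("GAPGK", 3, True),
            ("TAPAK", 3, False),
            ("PGK", 1, False),  # no room for the leading G-X
            ("XAPGK", 3, False),  # nonstandard residue never matches G
        ],
    )
    def test_hydroxyproline_context(self, pep, pos, expected):
        assert flag_hydroxyproline_context(pep, pos) is expected

    def test_hydroxyproline_requires_proline(self):
        with pytest.raises(ValueError):
            flag_hydroxyproline_context("GAPGK", 2)
        with pytest.raises(ValueError):
            flag_hydroxyproline_context("GAPGK", 9)

    @pytest.mark.parametrize(
        "pep,positions,expected",
        [
            ("LNGSK", [2], [2]),
            ("LNGPK", [2], []),
            ("KLN", [3], []),  # motif runs past the peptide end
            ("LNGTNKS", [2, 5], [2, 5]),
        ],
    )
    def test_deglycosylation_sites(self, pep, positions, expected):
        assert infer_deglycosylation_sites(pep, positions) == expected

    def test_deglycosylation_requires_asparagine(self):
        with pytest.raises(ValueError):
            infer_deglycosylation_sites("LAGSK", [2])
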