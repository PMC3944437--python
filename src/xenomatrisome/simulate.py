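"""Ground-truthed simulation of xenograft proteomics experiments.

The generator emulates the statistical structure the analysis assumes: two
tumor types, each profiled in two biological replicates; proteins drawn as
human/mouse ortholog pairs with controlled sequence divergence (so the split
between species-specific and species-shared tryptic peptides is under
experimental control); log-normal protein abundance with per-peptide
detection probability saturating in abundance; per-charge target and decoy
score distributions bounded at the 25-point score cap; and per-protein
ground-truth origin mixtures — tumor-only, stroma-only, or mixed with a known
human:mouse intensity ratio.

Ortholog substitutions never touch K, R, or P, so both orthologs share one
tryptic cleavage map and every tryptic peptide exists as an aligned pair:
either conserved (shared between species) or diverged (one human-specific and
one mouse-specific peptide).  Divergence therefore controls peptide identity
without disturbing ground-truth bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import matrisome as mat
from .filtering import PSM_COLUMNS
from .proteomes import (
    HUMAN,
    HUMAN_SPECIFIC,
    MOUSE,
    MOUSE_SPECIFIC,
    SHARED,
    ProteomeEntry,
    apply_equivalence,
    cleavage_fragments,
    reverse_decoy,
)
from .quantify import (
    BOTH_SIMILAR,
    BOTH_STROMA_DOMINANT,
    BOTH_TUMOR_DOMINANT,
    COARSE_CLASS,
    STROMA_ONLY,
    TUMOR_ONLY,
    UNDETERMINED,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: substitution targets: never K/R/P (cleavage map) and never I/L (isobaric)
_SUBSTITUTABLE_TO = np.array(list("ACDEFGHMNQSTVWY"))

ORIGIN_KINDS = (TUMOR_ONLY, STROMA_ONLY, "mixed")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated xenograft experiment.

    Defaults describe two tumor types x two biological replicates over 150
    ortholog pairs at 10% per-substitutable-residue divergence, with 60% of
    proteins common to both tumor types, a 35/25/40 split of tumor-only /
    stroma-only / mixed origins, and log-uniform mixing ratios up to 20-fold
    either way.
    """

    n_proteins: int = 150
    protein_length_range: tuple[int, int] = (150, 450)
    ortholog_divergence: float = 0.10
    fraction_shared_between_tumor_types: float = 0.6
    fraction_non_matrisome: float = 0.1
    origin_weights: dict[str, float] = field(
        default_factory=lambda: {TUMOR_ONLY: 0.35, STROMA_ONLY: 0.25, "mixed": 0.40}
    )
    origin_conservation: float = 0.7
    mixed_ratio_log10_range: tuple[float, float] = (0.0, 1.3)
    mixed_ratio_symmetric: bool = True
    abundance_log_mean: float = 16.0  # natural-log ion-current units
    abundance_log_sd: float = 1.5
    detection_p_max: float = 0.9
    detection_k_half: float = 2e6  # ion-current units at half-maximal detection
    score_target_means: dict[int, float] = field(
        default_factory=lambda: {2: 12.0, 3: 13.0, 4: 14.0}
    )
    score_target_sd: float = 4.0
    score_decoy_mean: float = 5.0
    score_decoy_sd: float = 2.5
    score_max: float = 25.0
    decoy_psm_fraction: float = 0.10
    intensity_noise_sigma: float = 0.5
    poor_quality_fraction: float = 0.02
    mod_variant_fraction: float = 0.05
    replicates_per_type: int = 2
    tumor_types: tuple[str, str] = ("A", "B")
    charges: tuple[int, ...] = (2, 3, 4)
    charge_weights: tuple[float, ...] = (0.5, 0.35, 0.15)
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    n_fractions: int = 1

    def validate(self) -> None:
        probs = {
            "ortholog_divergence": self.ortholog_divergence,
            "fraction_shared_between_tumor_types": self.fraction_shared_between_tumor_types,
            "fraction_non_matrisome": self.fraction_non_matrisome,
            "origin_conservation": self.origin_conservation,
            "detection_p_max": self.detection_p_max,
            "decoy_psm_fraction": self.decoy_psm_fraction,
            "poor_quality_fraction": self.poor_quality_fraction,
            "mod_variant_fraction": self.mod_variant_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.replicates_per_type < 2:
            raise ConfigError("the membership rule needs at least two replicates")
        if abs(sum(self.origin_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("origin_weights must sum to 1")
        if set(self.origin_weights) != set(ORIGIN_KINDS):
            raise ConfigError(f"origin_weights must have keys {ORIGIN_KINDS}")
        if self.intensity_noise_sigma < 0 or self.abundance_log_sd < 0:
            raise ConfigError("noise scales must be nonnegative")
        if len(self.charges) != len(self.charge_weights):
            raise ConfigError("charges and charge_weights must align")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["protein_length_range"] = list(self.protein_length_range)
        data["mixed_ratio_log10_range"] = list(self.mixed_ratio_log10_range)
        data["tumor_types"] = list(self.tumor_types)
        data["charges"] = list(self.charges)
        data["charge_weights"] = list(self.charge_weights)
        data["score_target_means"] = {int(k): float(v) for k, v in self.score_target_means.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("protein_length_range", "mixed_ratio_log10_range", "tumor_types", "charges", "charge_weights"):
            if key in data:
                data[key] = tuple(data[key])
        if "score_target_means" in data:
            data["score_target_means"] = {int(k): float(v) for k, v in data["score_target_means"].items()}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def noise_free(cls, **overrides) -> "SimulationConfig":
        """Exact-recovery conditions: full detection, no noise, no decoys,
        no modification variants, and mixing ratios outside (1/5, 5)."""
        base = dict(
            detection_p_max=1.0,
            detection_k_half=0.0,
            intensity_noise_sigma=0.0,
            decoy_psm_fraction=0.0,
            poor_quality_fraction=0.0,
            mod_variant_fraction=0.0,
            mixed_ratio_log10_range=(0.75, 1.3),
        )
        base.update(overrides)
        cfg = cls(**base)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# proteome pair


def simulate_proteome_pair(
    config: SimulationConfig, seed: int
) -> tuple[list[ProteomeEntry], list[ProteomeEntry], dict[str, str]]:
    """Paired databases of human proteins and their mouse orthologs.

    Each mouse ortholog derives from its human partner by independent
    substitution at rate ``ortholog_divergence`` on non-K/R/P positions;
    substitutions never create K/R/P (the tryptic map is preserved) nor I/L
    (isobaric with each other).  Deterministic in (config, seed).
    """
    config.validate()
    rng = np.random.default_rng([int(seed), 11])
    humans: list[ProteomeEntry] = []
    mice: list[ProteomeEntry] = []
    ortholog_map: dict[str, str] = {}
    lo, hi = config.protein_length_range
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(AMINO_ACIDS, size=length)
        mouse_seq = seq.copy()
        substitutable = ~np.isin(seq, list("KRP"))
        flip = substitutable & (rng.random(length) < config.ortholog_divergence)
        for pos in np.flatnonzero(flip):
            choices = _SUBSTITUTABLE_TO[_SUBSTITUTABLE_TO != seq[pos]]
            mouse_seq[pos] = rng.choice(choices)
        h_acc, m_acc = f"HUM{i:04d}", f"MOU{i:04d}"
        gene = f"GENE{i:04d}"
        humans.append(ProteomeEntry(h_acc, HUMAN, gene, "".join(seq)))
        mice.append(ProteomeEntry(m_acc, MOUSE, gene.capitalize(), "".join(mouse_seq)))
        ortholog_map[h_acc] = m_acc
    return humans, mice, ortholog_map


# ---------------------------------------------------------------------------
# deterministic per-protein design (shared with ground_truth_signature)


_CATEGORY_CYCLE = sorted(mat.CORE_CATEGORIES) + sorted(mat.ASSOCIATED_CATEGORIES)


def _protein_design(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic per-protein study design implied by the config.

    Protein i is annotated non-matrisome if it falls in the trailing
    ``fraction_non_matrisome`` block; matrisome categories cycle through the
    six divisions.  The leading ``fraction_shared_between_tumor_types`` block
    is present in both tumor types; the remainder alternates between the two.
    """
    n = config.n_proteins
    n_non = int(round(n * config.fraction_non_matrisome))
    n_shared = int(round(n * config.fraction_shared_between_tumor_types))
    rows = []
    alternate = 0
    for i in range(n):
        non_matrisome = i >= n - n_non
        if i < n_shared:
            in_a = in_b = True
        else:
            in_a = alternate % 2 == 0
            in_b = not in_a
            alternate += 1
        category = "none" if non_matrisome else _CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)]
        division = (
            mat.NON_MATRISOME
            if non_matrisome
            else (
                mat.CORE_MATRISOME
                if category in mat.CORE_CATEGORIES
                else mat.MATRISOME_ASSOCIATED
            )
        )
        rows.append(
            {
                "gene": f"GENE{i:04d}",
                "division": division,
                "category": category,
                "in_A": in_a,
                "in_B": in_b,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruth:
    """Everything the simulator intended, for checking the pipeline against.

    ``protein_table`` has one row per ortholog pair with its design
    (membership, annotation), its drawn origin class and mixing ratio per
    tumor type, and the realized peptide bookkeeping (how many aligned
    peptide pairs fall in the length bounds, and how many are species-
    specific under the global digest).  ``psm_provenance`` parallels each PSM
    table row-for-row with the generating protein and species.
    """

    config: SimulationConfig
    seed: int
    humans: list[ProteomeEntry]
    mice: list[ProteomeEntry]
    ortholog_map: dict[str, str]
    annotations: list[mat.MatrisomeAnnotation]
    protein_table: pd.DataFrame
    psm_provenance: dict[tuple[str, str], pd.DataFrame]

    def expected_matrisome(self, tumor_type: str) -> set[str]:
        """Genes intended to satisfy the membership rule under full detection."""
        t = self.protein_table
        col = f"in_{tumor_type}"
        mask = t[col] & (t["division"] != mat.NON_MATRISOME)
        mask &= t[f"n_detectable_{tumor_type}"] >= 2
        return set(t.loc[mask, "gene"].str.upper())

    def expected_venn(self) -> tuple[int, int, int]:
        a = self.expected_matrisome(self.config.tumor_types[0])
        b = self.expected_matrisome(self.config.tumor_types[1])
        return (len(a & b), len(a - b), len(b - a))

    def expected_origin(self, tumor_type: str, fold_threshold: float = 5.0) -> dict[str, str]:
        """Intended origin class per gene, given realized peptide specificity."""
        out: dict[str, str] = {}
        t = self.protein_table
        for row in t[t[f"in_{tumor_type}"]].itertuples(index=False):
            origin = getattr(row, f"origin_{tumor_type}")
            ratio = getattr(row, f"ratio_{tumor_type}")
            n_spec_h = row.n_specific_human
            n_spec_m = row.n_specific_mouse
            if origin == TUMOR_ONLY:
                cls = TUMOR_ONLY if n_spec_h > 0 else UNDETERMINED
            elif origin == STROMA_ONLY:
                cls = STROMA_ONLY if n_spec_m > 0 else UNDETERMINED
            else:
                if n_spec_h == 0 and n_spec_m == 0:
                    cls = UNDETERMINED
                elif n_spec_m == 0:
                    cls = TUMOR_ONLY
                elif n_spec_h == 0:
                    cls = STROMA_ONLY
                elif ratio >= fold_threshold:
                    cls = BOTH_TUMOR_DOMINANT
                elif ratio <= 1.0 / fold_threshold:
                    cls = BOTH_STROMA_DOMINANT
                else:
                    cls = BOTH_SIMILAR
            out[row.gene.upper()] = cls
        return out

    def expected_origin_shifts(self, fold_threshold: float = 5.0) -> tuple[set[str], set[str]]:
        """(same, shifted) gene sets over the shared expected matrisome, coarse classes."""
        ta, tb = self.config.tumor_types
        shared = self.expected_matrisome(ta) & self.expected_matrisome(tb)
        oa, ob = self.expected_origin(ta, fold_threshold), self.expected_origin(tb, fold_threshold)
        same, shifted = set(), set()
        for g in shared:
            ca, cb = COARSE_CLASS[oa[g]], COARSE_CLASS[ob[g]]
            if UNDETERMINED in (ca, cb):
                continue
            (same if ca == cb else shifted).add(g)
        return same, shifted


@dataclass(frozen=True)
class ExpectedSignature:
    """Config-level restatement of the expected downstream answer."""

    matrisome_size_a: int
    matrisome_size_b: int
    venn: tuple[int, int, int]  # shared, A-only, B-only
    origin_shift_count: int | None  # None when not determined by config alone


def ground_truth_signature(config: SimulationConfig) -> ExpectedSignature:
    """Expected membership sets and Venn counts implied by the config alone.

    Peptide-level stochastic effects are ignored here (every designed protein
    is assumed detectable); the origin-shift count is determined only when the
    config pins origins (a degenerate origin mixture, or full conservation
    between tumor types), otherwise it is ``None``.
    """
    config.validate()
    design = _protein_design(config)
    m = design["division"] != mat.NON_MATRISOME
    a = set(design.loc[m & design["in_A"], "gene"])
    b = set(design.loc[m & design["in_B"], "gene"])
    # coarse origin classes (tumor / stroma / both) are pinned when the origin
    # mixture is degenerate or when tumor type B always reuses type A's draw
    degenerate = any(abs(w - 1.0) < 1e-12 for w in config.origin_weights.values())
    pinned = degenerate or config.origin_conservation >= 1.0
    return ExpectedSignature(
        matrisome_size_a=len(a),
        matrisome_size_b=len(b),
        venn=(len(a & b), len(a - b), len(b - a)),
        origin_shift_count=0 if pinned else None,
    )


# ---------------------------------------------------------------------------
# PSM simulation


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int = 1) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _peptide_pairs(
    human: ProteomeEntry,
    mouse: ProteomeEntry,
    config: SimulationConfig,
) -> list[tuple[str, str]]:
    """Aligned in-bounds tryptic peptide pairs, deduplicated by sequence."""
    hf, mf = cleavage_fragments(human.sequence), cleavage_fragments(mouse.sequence)
    assert len(hf) == len(mf), "orthologs must share the cleavage map"
    pairs = []
    seen: set[tuple[str, str]] = set()
    for hp, mp in zip(hf, mf):
        if not (config.min_peptide_length <= len(hp) <= config.max_peptide_length):
            continue
        if (hp, mp) in seen:
            continue
        seen.add((hp, mp))
        pairs.append((hp, mp))
    return pairs


def simulate_psm_tables(
    config: SimulationConfig, seed: int
) -> tuple[dict[tuple[str, str], pd.DataFrame], GroundTruth]:
    """PSM tables (one per tumor type x replicate) plus full ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps (tumor_type,
    replicate_id) to a PSM DataFrame in the on-disk column order.
    """
    config.validate()
    humans, mice, ortholog_map = simulate_proteome_pair(config, seed)
    rng = np.random.default_rng([int(seed), 23])
    design = _protein_design(config)
    type_a, type_b = config.tumor_types

    # global species-specificity of every in-bounds peptide (I/L collapsed)
    pair_lists = [
        _peptide_pairs(h, m, config) for h, m in zip(humans, mice)
    ]
    human_set = {apply_equivalence(hp) for pairs in pair_lists for hp, _ in pairs}
    mouse_set = {apply_equivalence(mp) for pairs in pair_lists for _, mp in pairs}

    def label_h(pep: str) -> str:
        return SHARED if apply_equivalence(pep) in mouse_set else HUMAN_SPECIFIC

    def label_m(pep: str) -> str:
        return SHARED if apply_equivalence(pep) in human_set else MOUSE_SPECIFIC

    # per-protein origin, ratio, abundance per tumor type
    kinds = list(config.origin_weights)
    weights = np.array([config.origin_weights[k] for k in kinds])

    def draw_origin() -> tuple[str, float]:
        kind = kinds[int(rng.choice(len(kinds), p=weights))]
        if kind != "mixed":
            return kind, math.inf if kind == TUMOR_ONLY else 0.0
        lo, hi = config.mixed_ratio_log10_range
        u = rng.uniform(lo, hi)
        if config.mixed_ratio_symmetric and rng.random() < 0.5:
            u = -u
        return "mixed", float(10.0**u)

    records = []
    for i, (h, m) in enumerate(zip(humans, mice)):
        origin_a, ratio_a = draw_origin()
        if rng.random() < config.origin_conservation:
            origin_b, ratio_b = origin_a, ratio_a
        else:
            origin_b, ratio_b = draw_origin()
        pairs = pair_lists[i]
        n_spec_h = sum(1 for hp, _ in pairs if label_h(hp) == HUMAN_SPECIFIC)
        n_spec_m = sum(1 for _, mp in pairs if label_m(mp) == MOUSE_SPECIFIC)

        def n_detectable(origin: str) -> int:
            # distinct gene-level peptide sequences when everything is detected
            if origin == TUMOR_ONLY:
                return len({hp for hp, _ in pairs})
            if origin == STROMA_ONLY:
                return len({mp for _, mp in pairs})
            return len({hp for hp, _ in pairs} | {mp for _, mp in pairs})

        records.append(
            {
                "pair_index": i,
                "gene": design.loc[i, "gene"],
                "accession_human": h.accession,
                "accession_mouse": m.accession,
                "division": design.loc[i, "division"],
                "category": design.loc[i, "category"],
                "in_A": bool(design.loc[i, "in_A"]),
                "in_B": bool(design.loc[i, "in_B"]),
                "origin_A": origin_a,
                "origin_B": origin_b,
                "ratio_A": ratio_a,
                "ratio_B": ratio_b,
                "abundance_A": float(rng.lognormal(config.abundance_log_mean, config.abundance_log_sd)),
                "abundance_B": float(rng.lognormal(config.abundance_log_mean, config.abundance_log_sd)),
                "n_peptide_pairs": len(pairs),
                "n_specific_human": n_spec_h,
                "n_specific_mouse": n_spec_m,
                "n_detectable_A": n_detectable(origin_a),
                "n_detectable_B": n_detectable(origin_b),
            }
        )
    protein_table = pd.DataFrame(records)
    # rename membership columns to the configured tumor-type names
    protein_table = protein_table.rename(
        columns={
            "in_A": f"in_{type_a}",
            "in_B": f"in_{type_b}",
            "origin_A": f"origin_{type_a}",
            "origin_B": f"origin_{type_b}",
            "ratio_A": f"ratio_{type_a}",
            "ratio_B": f"ratio_{type_b}",
            "abundance_A": f"abundance_{type_a}",
            "abundance_B": f"abundance_{type_b}",
            "n_detectable_A": f"n_detectable_{type_a}",
            "n_detectable_B": f"n_detectable_{type_b}",
        }
    )

    annotations = [
        mat.MatrisomeAnnotation(row.gene, row.division, row.category)
        for row in design.itertuples(index=False)
    ]

    def detection_p(expected_intensity: float) -> float:
        if config.detection_k_half <= 0:
            return config.detection_p_max
        return config.detection_p_max * expected_intensity / (
            expected_intensity + config.detection_k_half
        )

    charge_w = np.asarray(config.charge_weights, dtype=float)
    charge_w = charge_w / charge_w.sum()

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    provenance: dict[tuple[str, str], pd.DataFrame] = {}
    decoy_peps_by_protein = {
        e.accession: [
            p
            for p in cleavage_fragments(reverse_decoy(e).sequence)
            if config.min_peptide_length <= len(p) <= config.max_peptide_length
        ]
        for e in humans + mice
    }
    target_sets = human_set | mouse_set

    for tumor_type in config.tumor_types:
        for rep in range(1, config.replicates_per_type + 1):
            rep_id = f"r{rep}"
            sample_id = f"{tumor_type}_{rep_id}"
            rows: list[dict] = []
            prov: list[dict] = []

            def emit(
                pep: str,
                intensity_expected: float,
                protein_acc: str,
                species: str,
                is_decoy: bool = False,
                score: float | None = None,
            ) -> None:
                charge = int(rng.choice(config.charges, p=charge_w))
                if score is None:
                    score = float(
                        _truncnorm(
                            rng,
                            config.score_target_means[charge],
                            config.score_target_sd,
                            0.0,
                            config.score_max,
                        )[0]
                    )
                noise = (
                    float(rng.lognormal(0.0, config.intensity_noise_sigma))
                    if config.intensity_noise_sigma > 0
                    else 1.0
                )
                fraction = (
                    f"f{int(rng.integers(1, config.n_fractions + 1))}"
                    if config.n_fractions > 1
                    else "f1"
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "replicate_id": rep_id,
                        "fraction_id": fraction,
                        "peptide": pep,
                        "modifications": "",
                        "charge": charge,
                        "score": score,
                        "precursor_intensity": intensity_expected * noise,
                        "good_isotope_quality": bool(
                            rng.random() >= config.poor_quality_fraction
                        ),
                        "is_decoy": is_decoy,
                    }
                )
                prov.append({"protein": protein_acc, "species": species})
                if (
                    not is_decoy
                    and config.mod_variant_fraction > 0
                    and "M" in pep
                    and rng.random() < config.mod_variant_fraction
                ):
                    pos = pep.index("M") + 1
                    rows.append(
                        {
                            **rows[-1],
                            "modifications": f"{pos}:oxidation_M",
                            "score": max(0.0, score - 2.0),
                            "precursor_intensity": 0.3
                            * intensity_expected
                            * (
                                float(rng.lognormal(0.0, config.intensity_noise_sigma))
                                if config.intensity_noise_sigma > 0
                                else 1.0
                            ),
                        }
                    )
                    prov.append({"protein": protein_acc, "species": species})

            for row in protein_table.itertuples(index=False):
                if not getattr(row, f"in_{tumor_type}"):
                    continue
                origin = getattr(row, f"origin_{tumor_type}")
                ratio = getattr(row, f"ratio_{tumor_type}")
                abundance = getattr(row, f"abundance_{tumor_type}")
                if origin == TUMOR_ONLY:
                    a_h, a_m = abundance, 0.0
                elif origin == STROMA_ONLY:
                    a_h, a_m = 0.0, abundance
                else:
                    a_h = abundance * ratio / (1.0 + ratio)
                    a_m = abundance / (1.0 + ratio)
                # detection saturates in the protein's total abundance, so the
                # minor species' ions are sampled at the same rate as the
                # major's and the intensity ratio stays unbiased
                p_det = detection_p(abundance)
                for hp, mp in pair_lists[row.pair_index]:
                    shared = label_h(hp) == SHARED and label_m(mp) == SHARED
                    if shared and hp == mp:
                        if abundance > 0 and rng.random() < p_det:
                            emit(hp, a_h + a_m, row.accession_human, HUMAN)
                    else:
                        if a_h > 0 and rng.random() < p_det:
                            emit(hp, a_h, row.accession_human, HUMAN)
                        if a_m > 0 and rng.random() < p_det:
                            emit(mp, a_m, row.accession_mouse, MOUSE)

            n_targets = len(rows)
            f = config.decoy_psm_fraction
            n_decoys = int(round(f / (1.0 - f) * n_targets)) if f < 1 else 0
            all_accs = list(decoy_peps_by_protein)
            made = 0
            while made < n_decoys:
                acc = all_accs[int(rng.integers(len(all_accs)))]
                peps = decoy_peps_by_protein[acc]
                if not peps:
                    continue
                pep = peps[int(rng.integers(len(peps)))]
                if apply_equivalence(pep) in target_sets:
                    continue  # decoy peptide colliding with a target sequence
                intensity = float(rng.lognormal(config.abundance_log_mean - 3.0, 1.0))
                charge = int(rng.choice(config.charges, p=charge_w))
                score = float(
                    _truncnorm(
                        rng,
                        config.score_decoy_mean,
                        config.score_decoy_sd,
                        0.0,
                        config.score_max,
                    )[0]
                )
                emit(pep, intensity, f"rev_{acc}", "decoy", is_decoy=True, score=score)
                made += 1

            df = pd.DataFrame(rows, columns=PSM_COLUMNS)
            tables[(tumor_type, rep_id)] = df
            provenance[(tumor_type, rep_id)] = pd.DataFrame(prov)

    truth = GroundTruth(
        config=config,
        seed=int(seed),
        humans=humans,
        mice=mice,
        ortholog_map=ortholog_map,
        annotations=annotations,
        protein_table=protein_table,
        psm_provenance=provenance,
    )
    return tables, truth


def write_simulation(
    outdir: str | Path,
    tables: Mapping[tuple[str, str], pd.DataFrame],
    truth: GroundTruth,
) -> None:
    """Write FASTA pair, annotation, PSM tables, and ground truth as text."""
    from .filtering import write_psm_table
    from .proteomes import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "human.fasta", truth.humans)
    write_fasta(outdir / "mouse.fasta", truth.mice)
    mat.write_annotation(outdir / "annotation.tsv", truth.annotations)
    for (tumor_type, rep), df in tables.items():
        write_psm_table(outdir / f"psms_{tumor_type}_{rep}.tsv", df)
    truth.protein_table.to_csv(outdir / "ground_truth_proteins.tsv", sep="\t", index=False)
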