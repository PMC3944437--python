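"""Spectral-level target-decoy FDR thresholding and sequence-motif QC.

PSM (peptide-spectrum match) tables are plain tab-separated text with one row
per confidently scored spectrum.  Identification confidence is controlled the
way ion-trap search pipelines do it: a score threshold is chosen separately
for each precursor charge state (2, 3, 4) in each LC-MS/MS run so that the
estimated false-discovery rate — decoy matches divided by target matches above
the threshold — does not exceed a target level (1.6% by default).  Charge-1
and charge->4 precursors are excluded before thresholding.

Two small motif checks support downstream QC of modified residues:
hydroxyproline is only credible inside the collagen-like G-X-P-G context, and
a deamidated Asn in an N-X-[S/T] sequon marks a site where N-linked glycans
were enzymatically removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MAX_PEPTIDE_SCORE = 25.0
DEFAULT_SPECTRAL_FDR = 0.016
ALLOWED_CHARGES = (2, 3, 4)

#: columns of the on-disk PSM table, in order
PSM_COLUMNS = [
    "sample_id",
    "replicate_id",
    "fraction_id",
    "peptide",
    "modifications",
    "charge",
    "score",
    "precursor_intensity",
    "good_isotope_quality",
    "is_decoy",
]

#: modification kind -> residue it must sit on
MODIFICATION_RESIDUES = {
    "oxidation_M": "M",
    "deamidation_N": "N",
    "pyroGlu_Q": "Q",
    "hydroxylation_P": "P",
    "carbamidomethyl_C": "C",
}


class FilterError(ValueError):
    """Invalid PSM table content or inconsistent thresholding request."""


def parse_modifications(spec: str) -> list[tuple[int, str]]:
    """Parse a 'pos:kind;pos:kind' modification string (1-based positions)."""
    if not spec or (isinstance(spec, float) and math.isnan(spec)):
        return []
    out = []
    for token in str(spec).split(";"):
        pos, kind = token.split(":")
        out.append((int(pos), kind))
    return out


def format_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{p}:{k}" for p, k in mods)


def validate_psm_table(psms: pd.DataFrame) -> None:
    """Check schema, score range, and modification consistency.

    Raises :class:`FilterError` with the offending row index on failure.
    """
    missing = [c for c in PSM_COLUMNS if c not in psms.columns]
    if missing:
        raise FilterError(f"PSM table missing columns {missing}")
    bad_score = psms.index[(psms["score"] < 0) | (psms["score"] > MAX_PEPTIDE_SCORE)]
    if len(bad_score):
        raise FilterError(f"score outside [0, {MAX_PEPTIDE_SCORE}] at rows {list(bad_score[:5])}")
    if (psms["precursor_intensity"] < 0).any():
        raise FilterError("negative precursor intensity")
    for idx, pep, spec in psms[["peptide", "modifications"]].itertuples():
        for pos, kind in parse_modifications(spec):
            if kind not in MODIFICATION_RESIDUES:
                raise FilterError(f"row {idx}: unknown modification kind {kind!r}")
            if not (1 <= pos <= len(pep)):
                raise FilterError(f"row {idx}: modification position {pos} outside peptide")
            if pep[pos - 1] != MODIFICATION_RESIDUES[kind]:
                raise FilterError(
                    f"row {idx}: {kind} at position {pos} but residue is {pep[pos - 1]}"
                )


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"modifications": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("good_isotope_quality", "is_decoy"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, "1": True, "0": False})
        df[col] = df[col].astype(bool)
    df["charge"] = df["charge"].astype(int)
    df["score"] = df["score"].astype(float)
    df["precursor_intensity"] = df["precursor_intensity"].astype(float)
    validate_psm_table(df)
    return df


def write_psm_table(path: str | Path, psms: pd.DataFrame) -> None:
    psms.to_csv(path, sep="\t", index=False, columns=PSM_COLUMNS)


def run_ids(psms: pd.DataFrame) -> pd.Series:
    """One LC-MS/MS run per (sample, fraction); thresholds are chosen per run."""
    return psms["sample_id"].astype(str) + "|" + psms["fraction_id"].astype(str)


def restrict_charges(
    psms: pd.DataFrame, charges: Iterable[int] = ALLOWED_CHARGES
) -> pd.DataFrame:
    """Drop precursors whose charge is outside the analyzable set {2, 3, 4}."""
    return psms[psms["charge"].isin(list(charges))].copy()


def spectral_fdr_threshold(
    psms: pd.DataFrame, charge: int, target_fdr: float = DEFAULT_SPECTRAL_FDR
) -> float:
    """Smallest observed score t with decoys/targets at score >= t <= target_fdr.

    The candidate grid is the set of observed scores at the given charge.  If
    no candidate satisfies the target, +inf is returned (everything filtered).
    Raises :class:`FilterError` when no target PSM carries that charge.
    """
    sub = psms[psms["charge"] == charge]
    targets = np.sort(sub.loc[~sub["is_decoy"], "score"].to_numpy())
    decoys = np.sort(sub.loc[sub["is_decoy"], "score"].to_numpy())
    if targets.size == 0:
        raise FilterError(f"no target PSMs at charge {charge}")
    for t in np.unique(np.concatenate([targets, decoys])):
        n_t = targets.size - np.searchsorted(targets, t, side="left")
        n_d = decoys.size - np.searchsorted(decoys, t, side="left")
        if n_t > 0 and n_d / n_t <= target_fdr:
            return float(t)
    return math.inf


def compute_spectral_thresholds(
    psms: pd.DataFrame,
    target_fdr: float = DEFAULT_SPECTRAL_FDR,
    per_run: bool = True,
) -> dict[tuple[str, int], float]:
    """Thresholds keyed by (run id, charge); run id is '<sample>|<fraction>'.

    With ``per_run=False`` a single pooled run labelled ``'*'`` is used.
    """
    work = psms.copy()
    work["_run"] = run_ids(work) if per_run else "*"
    thresholds: dict[tuple[str, int], float] = {}
    for (run, charge), sub in work.groupby(["_run", "charge"], sort=True):
        thresholds[(str(run), int(charge))] = spectral_fdr_threshold(
            sub, int(charge), target_fdr
        )
    return thresholds


def filter_psms(
    psms: pd.DataFrame,
    per_charge_thresholds: Mapping[tuple[str, int], float],
    per_run: bool = True,
) -> pd.DataFrame:
    """Retain PSMs whose score meets the threshold of their (run, charge).

    Raises :class:`FilterError` for an observed (run, charge) with no
    threshold provided.
    """
    runs = run_ids(psms) if per_run else pd.Series("*", index=psms.index)
    keep = np.zeros(len(psms), dtype=bool)
    for i, (run, charge, score) in enumerate(
        zip(runs, psms["charge"], psms["score"])
    ):
        key = (str(run), int(charge))
        if key not in per_charge_thresholds:
            raise FilterError(f"no threshold for run {run!r}, charge {charge}")
        keep[i] = score >= per_charge_thresholds[key]
    return psms[keep].copy()


@dataclass(frozen=True)
class ChargeFilterReport:
    run: str
    charge: int
    n_targets: int
    n_decoys: int
    threshold: float
    retained_targets: int
    retained_decoys: int
    achieved_fdr: float


def filtering_report(
    psms: pd.DataFrame,
    thresholds: Mapping[tuple[str, int], float],
    per_run: bool = True,
) -> pd.DataFrame:
    """Per (run, charge) counts, threshold, and achieved decoy/target FDR."""
    work = psms.copy()
    work["_run"] = run_ids(work) if per_run else "*"
    rows = []
    for (run, charge), sub in work.groupby(["_run", "charge"], sort=True):
        t = thresholds[(str(run), int(charge))]
        above = sub[sub["score"] >= t]
        r_t = int((~above["is_decoy"]).sum())
        r_d = int(above["is_decoy"].sum())
        rows.append(
            ChargeFilterReport(
                run=str(run),
                charge=int(charge),
                n_targets=int((~sub["is_decoy"]).sum()),
                n_decoys=int(sub["is_decoy"].sum()),
                threshold=float(t),
                retained_targets=r_t,
                retained_decoys=r_d,
                achieved_fdr=(r_d / r_t) if r_t else 0.0,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def flag_hydroxyproline_context(peptide_sequence: str, position: int) -> bool:
    """True iff the proline at 1-based ``position`` sits in a G-X-P-G context.

    Hydroxyproline is expected only inside collagen-like GXPG motifs; a
    hydroxylation call outside that context is suspect.  Raises ``ValueError``
    if the position is out of range or not a proline.
    """
    p = position
    if not (1 <= p <= len(peptide_sequence)):
        raise ValueError(f"position {p} outside peptide of length {len(peptide_sequence)}")
    if peptide_sequence[p - 1] != "P":
        raise ValueError(f"residue at position {p} is {peptide_sequence[p - 1]}, not P")
    if p < 3 or p + 1 > len(peptide_sequence):
        return False
    return peptide_sequence[p - 3] == "G" and peptide_sequence[p] == "G"


def infer_deglycosylation_sites(
    peptide_sequence: str, deamidated_positions: Iterable[int]
) -> list[int]:
    """Deamidated Asn positions inside an N-X-[S/T] sequon.

    PNGaseF deglycosylation converts glycosylated Asn to Asp; a deamidated N
    whose position p has S or T at p+2 likely marks such a removed-glycan
    site.  Positions must point at N residues (1-based).
    """
    sites = []
    for p in sorted(set(deamidated_positions)):
        if not (1 <= p <= len(peptide_sequence)) or peptide_sequence[p - 1] != "N":
            raise ValueError(f"position {p} is not an N residue")
        if p + 2 <= len(peptide_sequence) and peptide_sequence[p + 1] in ("S", "T"):
            sites.append(p)
    return sites
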