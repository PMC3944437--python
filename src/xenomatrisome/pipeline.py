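"""End-to-end pipeline: digest -> FDR filter -> inference -> signatures.

The pipeline consumes a paired human/mouse database, one PSM table per
(tumor type, biological replicate), and a matrisome annotation table, and
produces per-type matrisomes, per-gene tumor/stroma origin calls, and the
two-type comparison.  Every intermediate table can be written as TSV next to
a machine-readable JSON run summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import filtering, inference, quantify, signatures
from .matrisome import AnnotationTable, load_annotation
from .proteomes import (
    DEFAULT_EQUIVALENCE,
    HUMAN,
    MOUSE,
    ProteomeEntry,
    apply_equivalence,
    build_digest_index,
    read_proteomes,
    with_decoys,
)

logger = logging.getLogger("xenomatrisome")


class PipelineError(RuntimeError):
    """Stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    """Every tunable of the analysis with its default.

    Defaults mirror the reference workflow: trypsin with two missed
    cleavages, spectral FDR 1.6% per charge state 2/3/4 per run, shared-
    peptide grouping strictly above 8 residues, protein score >= 20 at
    protein-level FDR 0, and the fivefold origin rule.
    """

    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    spectral_fdr: float = 0.016
    charges: tuple[int, ...] = (2, 3, 4)
    per_run_thresholds: bool = True
    grouping_min_length: int = 8
    min_protein_score: float = 20.0
    max_protein_fdr: float = 0.0
    fold_threshold: float = 5.0
    coarse_shift_classes: bool = True
    merge_asn_asp: bool = False  # N≡D equivalence for deamidation ambiguity

    @property
    def equivalence(self) -> tuple[frozenset[str], ...]:
        classes = list(DEFAULT_EQUIVALENCE)
        if self.merge_asn_asp:
            classes.append(frozenset("ND"))
        return tuple(classes)


@dataclass
class TumorTypeResult:
    """Intermediates for one tumor type."""

    tumor_type: str
    retained_psms: pd.DataFrame
    filter_report: pd.DataFrame
    subgroups: list[inference.ProteinSubgroup]
    species_labels: dict[str, str]
    gene_replicate_counts: dict[str, tuple[int, int]]
    matrisome: dict[str, signatures.MatrisomeProtein]
    origin_calls: dict[str, quantify.OriginCall]


@dataclass
class PipelineResult:
    signature: signatures.SignatureResult
    per_type: dict[str, TumorTypeResult]
    params: PipelineParams

    def summary(self) -> dict:
        out = self.signature.summary()
        out["stages"] = {
            t: {
                "retained_psms": int(len(r.retained_psms)),
                "reported_subgroups": len(r.subgroups),
                "matrisome_size": len(r.matrisome),
            }
            for t, r in self.per_type.items()
        }
        out["params"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self.params).items()
        }
        return out


def _species_label_map(
    peptides: Sequence[str], human_index, mouse_index, equivalence
) -> dict[str, str]:
    from .proteomes import classify_species_specificity

    labels: dict[str, str] = {}
    for pep in peptides:
        try:
            labels[pep] = classify_species_specificity(
                pep, human_index, mouse_index, equivalence
            )
        except KeyError:
            labels[pep] = "decoy"  # only decoy-digest peptides miss both indices
    return labels


def _gene_replicate_counts(
    subgroups: Sequence[inference.ProteinSubgroup],
    retained: pd.DataFrame,
    replicate_ids: Sequence[str],
) -> dict[str, tuple[int, int]]:
    """Distinct peptides per gene per biological replicate."""
    pep_by_rep: dict[str, set[str]] = {
        rep: set(retained.loc[retained["replicate_id"] == rep, "peptide"])
        for rep in replicate_ids
    }
    gene_peps: dict[str, set[str]] = {}
    for sg in subgroups:
        gene_peps.setdefault(sg.gene_symbol.upper(), set()).update(
            sg.distinct_peptides
        )
    return {
        gene: tuple(len(peps & pep_by_rep[rep]) for rep in replicate_ids)
        for gene, peps in gene_peps.items()
    }


def run_pipeline(
    humans: Sequence[ProteomeEntry],
    mice: Sequence[ProteomeEntry],
    psm_tables: Mapping[tuple[str, str], pd.DataFrame],
    annotation: AnnotationTable,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full species-resolved matrisome analysis.

    ``psm_tables`` maps (tumor_type, replicate_id) to a PSM table; exactly
    two tumor types with two replicates each are expected.  When ``outdir``
    is given, every intermediate table and a JSON run summary are written.
    """
    params = params or PipelineParams()
    tumor_types = sorted({t for t, _ in psm_tables})
    if len(tumor_types) != 2:
        raise PipelineError("config", f"expected two tumor types, got {tumor_types}")

    logger.info("digesting databases (%d human, %d mouse entries)", len(humans), len(mice))
    digest_kw = dict(
        max_missed_cleavages=params.max_missed_cleavages,
        min_length=params.min_peptide_length,
        max_length=params.max_peptide_length,
        equivalence=params.equivalence,
    )
    try:
        human_index = build_digest_index(humans, HUMAN, **digest_kw)
        mouse_index = build_digest_index(mice, MOUSE, **digest_kw)
        all_entries = with_decoys(humans) + with_decoys(mice)
        combined_index = build_digest_index(all_entries, HUMAN, **digest_kw)
        entry_map = {e.accession: e for e in all_entries}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("digest", str(exc)) from exc

    def parents(pep: str) -> frozenset[str]:
        return frozenset(
            combined_index.peptides.get(apply_equivalence(pep, params.equivalence), ())
        )

    per_type: dict[str, TumorTypeResult] = {}
    for tumor_type in tumor_types:
        reps = sorted(rep for t, rep in psm_tables if t == tumor_type)
        if len(reps) != 2:
            raise PipelineError(
                "config", f"tumor type {tumor_type} needs two replicates, got {reps}"
            )
        pooled = pd.concat(
            [psm_tables[(tumor_type, rep)] for rep in reps], ignore_index=True
        )
        try:
            filtering.validate_psm_table(pooled)
            pooled = filtering.restrict_charges(pooled, params.charges)
            thresholds = filtering.compute_spectral_thresholds(
                pooled, params.spectral_fdr, per_run=params.per_run_thresholds
            )
            retained = filtering.filter_psms(
                pooled, thresholds, per_run=params.per_run_thresholds
            )
            report = filtering.filtering_report(
                pooled, thresholds, per_run=params.per_run_thresholds
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("spectra_filter", str(exc)) from exc
        logger.info(
            "%s: %d/%d PSMs retained at spectral FDR %.3f",
            tumor_type,
            len(retained),
            len(pooled),
            params.spectral_fdr,
        )

        try:
            distinct = inference.distinct_peptides(retained)
            pep_parents = {pep: parents(pep) for pep in distinct}
            subgroups = inference.group_proteins(
                distinct, entry_map, pep_parents, params.grouping_min_length
            )
            reported = inference.protein_level_filter(
                subgroups, params.min_protein_score, params.max_protein_fdr
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("inference", str(exc)) from exc
        logger.info(
            "%s: %d subgroups reported (of %d grouped)",
            tumor_type,
            len(reported),
            len(subgroups),
        )

        labels = _species_label_map(
            list(distinct), human_index, mouse_index, params.equivalence
        )
        counts = _gene_replicate_counts(reported, retained, reps)
        mtype = signatures.build_matrisome(counts, annotation)
        quantifiable = {
            gene for gene, c in counts.items() if quantify.protein_quantifiable(c)
        }
        calls = quantify.gene_origin_calls(
            [sg for sg in reported if sg.gene_symbol.upper() in quantifiable],
            retained[~retained["is_decoy"]],
            labels,
            params.fold_threshold,
        )
        per_type[tumor_type] = TumorTypeResult(
            tumor_type=tumor_type,
            retained_psms=retained,
            filter_report=report,
            subgroups=reported,
            species_labels=labels,
            gene_replicate_counts=counts,
            matrisome=mtype,
            origin_calls=calls,
        )

    type_a, type_b = tumor_types
    result_sig = signatures.compare_matrisomes(
        per_type[type_a].matrisome, per_type[type_b].matrisome, type_a, type_b
    )
    result_sig.origin_calls_a = per_type[type_a].origin_calls
    result_sig.origin_calls_b = per_type[type_b].origin_calls
    same, shifted, indet = signatures.detect_origin_shifts(
        result_sig.shared,
        result_sig.origin_calls_a,
        result_sig.origin_calls_b,
        coarse=params.coarse_shift_classes,
    )
    result_sig.origin_same = same
    result_sig.origin_shifted = shifted
    result_sig.origin_indeterminate = indet

    result = PipelineResult(signature=result_sig, per_type=per_type, params=params)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every intermediate table and the JSON run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tumor_type, r in result.per_type.items():
        r.filter_report.to_csv(outdir / f"filter_report_{tumor_type}.tsv", sep="\t", index=False)
        inference.subgroup_table(r.subgroups, r.species_labels).to_csv(
            outdir / f"subgroups_{tumor_type}.tsv", sep="\t", index=False
        )
        signatures.matrisome_table(r.matrisome).to_csv(
            outdir / f"matrisome_{tumor_type}.tsv", sep="\t", index=False
        )
        quantify.origin_table(r.origin_calls, tumor_type).to_csv(
            outdir / f"origin_{tumor_type}.tsv", sep="\t", index=False
        )
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# config-file entry point


def run_from_config(config_path: str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """Run the pipeline from a YAML run configuration.

    The config either simulates inputs (``simulation: {seed: ..., ...}``) or
    names them::

        inputs:
          human_fasta: human.fasta
          mouse_fasta: mouse.fasta
          annotation: annotation.tsv
          psm_tables:
            - {tumor_type: A, replicate: r1, path: psms_A_r1.tsv}
            ...
        params: {fold_threshold: 5.0, ...}
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    params = PipelineParams(**{
        k: (tuple(v) if k == "charges" else v) for k, v in (cfg.get("params") or {}).items()
    })

    if "simulation" in cfg:
        from .simulate import SimulationConfig, simulate_psm_tables

        sim_cfg = dict(cfg["simulation"])
        seed = int(sim_cfg.pop("seed", 0))
        sim = SimulationConfig(**sim_cfg) if sim_cfg else SimulationConfig()
        sim.validate()
        tables, truth = simulate_psm_tables(sim, seed)
        annotation = AnnotationTable(
            {a.gene_symbol: a for a in truth.annotations}
        )
        return run_pipeline(truth.humans, truth.mice, tables, annotation, params, outdir)

    if "inputs" not in cfg:
        raise PipelineError("config", "config needs an 'inputs' or 'simulation' section")
    inputs = cfg["inputs"]
    for key in ("human_fasta", "mouse_fasta", "annotation", "psm_tables"):
        if key not in inputs:
            raise PipelineError("config", f"missing input {key!r}")
    for key in ("human_fasta", "mouse_fasta", "annotation"):
        if not Path(inputs[key]).exists():
            raise PipelineError("config", f"input file not found: {inputs[key]}")
    humans, mice = read_proteomes(inputs["human_fasta"], inputs["mouse_fasta"])
    annotation = load_annotation(inputs["annotation"])
    tables = {}
    for spec in inputs["psm_tables"]:
        if not Path(spec["path"]).exists():
            raise PipelineError("config", f"PSM table not found: {spec['path']}")
        tables[(str(spec["tumor_type"]), str(spec["replicate"]))] = filtering.read_psm_table(
            spec["path"]
        )
    return run_pipeline(humans, mice, tables, annotation, params, outdir)
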