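"""End-to-end orchestration: load/simulate -> filter -> call -> specificity
-> validation matching -> annotation -> eQTL -> survival.

Every stage logs a machine-readable count so the funnel from raw segment
calls down to validated regions can be audited, and all outputs are
written as deterministic, stably sorted tab-separated tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import association, gene_annotation, recurrent_caller, segment_io
from .association import EqtlResult, NoContrastError, SurvivalResult
from .gene_annotation import GeneModel, MutationMatrix
from .recurrent_caller import RecurrentRegion
from .segment_io import CNASegment, GAIN, LOSS, OLD, PatientRecord, YOUNG
from .synthetic_cohort import CohortBundle, SimConfig, simulate_paired_experiment

logger = logging.getLogger("cnarec.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds, policies and input sources for one pipeline run.

    Exactly one of ``simulate`` / ``inputs`` must be set.  ``inputs`` maps
    the keys discovery_segments, validation_segments, discovery_clinical,
    validation_clinical, discovery_expression, validation_expression and
    gene_models to file paths.
    """

    simulate: SimConfig | None = None
    inputs: Mapping[str, str] | None = None
    min_probes: int = 10
    min_seg_size: int = 1000
    min_clique: int = 2
    min_patients: int = 5
    min_mcr_size: int = 1000
    young_cutoff: float = 45.0
    alpha: float = 0.05
    specificity_policy: str = "any-overlap"
    gene_assignment: str = "inner"  # or "outer"
    run_eqtl: bool = True
    run_survival: bool = True
    out_dir: str | Path = "cnarec_out"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineError(
                "config: exactly one of a simulate block or input paths is required"
            )
        for name in ("min_probes", "min_clique", "min_patients"):
            if getattr(self, name) < 1:
                raise PipelineError(f"config: {name} must be >= 1")
        for name in ("min_seg_size", "min_mcr_size", "young_cutoff", "alpha"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")
        if self.gene_assignment not in ("inner", "outer"):
            raise PipelineError("config: gene_assignment must be 'inner' or 'outer'")


@dataclass
class CohortData:
    label: str
    segments: list[CNASegment]
    patients: list[PatientRecord]
    expression: pd.DataFrame | None


@dataclass
class PipelineResult:
    counts: dict
    validated_regions: list[RecurrentRegion]
    young_specific: dict[str, list[RecurrentRegion]]  # "discovery"/"validation" -> regions
    mutation_matrices: dict[str, MutationMatrix]
    eqtl_results: list[EqtlResult]
    survival_results: list[SurvivalResult]
    out_dir: Path


_INPUT_KEYS = [
    "discovery_segments",
    "validation_segments",
    "discovery_clinical",
    "validation_clinical",
]


def _load_cohorts(config: PipelineConfig) -> tuple[CohortData, CohortData, list[GeneModel]]:
    if config.simulate is not None:
        disc, val = simulate_paired_experiment(config.simulate)
        return (
            CohortData(disc.label, disc.segments, disc.patients, disc.expression),
            CohortData(val.label, val.segments, val.patients, val.expression),
            disc.gene_models,
        )
    inputs = dict(config.inputs or {})
    missing = [k for k in _INPUT_KEYS if k not in inputs]
    if missing:
        raise PipelineError(f"stage load: missing input paths: {', '.join(missing)}")
    cohorts = []
    for label in ("discovery", "validation"):
        segs = segment_io.read_segments(inputs[f"{label}_segments"])
        patients = segment_io.read_clinical(inputs[f"{label}_clinical"])
        expr = None
        key = f"{label}_expression"
        if key in inputs:
            expr = association.read_expression(inputs[key])
        cohorts.append(CohortData(label, segs, patients, expr))
    genes: list[GeneModel] = []
    if "gene_models" in inputs:
        genes = gene_annotation.load_gene_models(inputs["gene_models"])
    return cohorts[0], cohorts[1], genes


def _young_patients(cohort: CohortData, cutoff: float) -> list[PatientRecord]:
    return [p for p in cohort.patients if p.age_group(cutoff) == YOUNG]


def call_young_specific(
    cohort: CohortData, config: PipelineConfig, counts: dict
) -> dict[str, list[RecurrentRegion]]:
    """Filter, partition and call regions for one cohort; return the
    young-specific regions per alteration type."""
    label = cohort.label
    filtered = segment_io.filter_segments(
        cohort.segments, min_probes=config.min_probes, min_size=config.min_seg_size
    )
    counts[f"{label}.segments_raw"] = len(cohort.segments)
    counts[f"{label}.segments_filtered"] = len(filtered)
    buckets = segment_io.partition_cohort(filtered, cohort.patients, config.young_cutoff)

    regions: dict[tuple[str, str], list[RecurrentRegion]] = {}
    for (group, alt_type), segs in buckets.items():
        counts[f"{label}.{group}.{alt_type}.segments"] = len(segs)
        regions[(group, alt_type)] = recurrent_caller.call_recurrent_regions(
            segs,
            min_clique=config.min_clique,
            min_patients=config.min_patients,
            min_mcr_size=config.min_mcr_size,
            cohort=label,
        )
        counts[f"{label}.{group}.{alt_type}.regions"] = len(regions[(group, alt_type)])

    young_specific: dict[str, list[RecurrentRegion]] = {}
    for alt_type in (GAIN, LOSS):
        young_specific[alt_type] = recurrent_caller.group_specific_regions(
            regions[(YOUNG, alt_type)],
            regions[(OLD, alt_type)],
            policy=config.specificity_policy,
        )
        counts[f"{label}.young_specific.{alt_type}.regions"] = len(young_specific[alt_type])
        logger.info(
            "%s %s: %d young regions -> %d young-specific",
            label, alt_type,
            len(regions[(YOUNG, alt_type)]), len(young_specific[alt_type]),
        )
    return young_specific


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write tables plus a counts log to out_dir."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    try:
        discovery, validation, gene_models = _load_cohorts(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    specific = {}
    for cohort in (discovery, validation):
        try:
            specific[cohort.label] = call_young_specific(cohort, config, counts)
        except Exception as exc:
            raise PipelineError(f"stage call[{cohort.label}]: {exc}") from exc

    validated: list[RecurrentRegion] = []
    for alt_type in (GAIN, LOSS):
        matched = recurrent_caller.match_discovery_validation(
            specific["discovery"][alt_type], specific["validation"][alt_type]
        )
        counts[f"validated.{alt_type}.regions"] = len(matched)
        validated.extend(matched)
    validated.sort(key=RecurrentRegion.sort_key)

    if gene_models:
        validated = gene_annotation.annotate_regions(
            validated, gene_models, use_outer=config.gene_assignment == "outer"
        )
    counts["validated.regions_with_genes"] = sum(1 for r in validated if r.genes)

    # Per-cohort young mutation matrices (the oncoprint-style export).
    filt = {
        c.label: segment_io.filter_segments(
            c.segments, min_probes=config.min_probes, min_size=config.min_seg_size
        )
        for c in (discovery, validation)
    }
    matrices: dict[str, MutationMatrix] = {}
    for cohort in (discovery, validation):
        young = _young_patients(cohort, config.young_cutoff)
        matrices[cohort.label] = gene_annotation.build_mutation_matrix(
            validated, filt[cohort.label], young
        )

    # Pooled young patients across cohorts for the association stages.
    pooled_patients = _young_patients(discovery, config.young_cutoff) + _young_patients(
        validation, config.young_cutoff
    )
    pooled_segments = filt["discovery"] + filt["validation"]
    pooled_expression = None
    if discovery.expression is not None and validation.expression is not None:
        pooled_expression = pd.concat(
            [discovery.expression, validation.expression], axis=1, join="inner"
        )

    eqtl_results: list[EqtlResult] = []
    survival_results: list[SurvivalResult] = []
    gene_regions = [(g, r) for r in validated for g in r.genes]
    if config.run_eqtl or config.run_survival:
        if pooled_expression is None and gene_regions:
            raise PipelineError(
                "stage eqtl/survival: expression matrices are required but missing"
            )
    seen: set[tuple[str, str]] = set()
    for gene, region in gene_regions:
        key = (gene, region.alteration_type)
        if key in seen:
            continue
        seen.add(key)
        if pooled_expression is None or gene not in pooled_expression.index:
            logger.warning("gene %s absent from the expression matrix; skipped", gene)
            continue
        ids = [p.patient_id for p in pooled_patients if p.patient_id in pooled_expression.columns]
        patients = [p for p in pooled_patients if p.patient_id in ids]
        expr = pooled_expression.loc[gene, ids].astype(float)
        keep = expr.notna()
        if not keep.all():
            logger.warning(
                "gene %s: dropping %d samples with missing expression",
                gene, int((~keep).sum()),
            )
        ids_kept = [i for i, k in zip(ids, keep) if k]
        patients = [p for p in patients if p.patient_id in set(ids_kept)]
        expr = expr[keep]
        status = gene_annotation.carrier_status(region, pooled_segments, patients)

        if config.run_eqtl:
            try:
                binary = association.binarize_by_mean(expr.to_numpy())
                eqtl_results.append(
                    association.eqtl_test(
                        binary, status.to_numpy(), gene=gene,
                        alteration_type=region.alteration_type,
                    )
                )
            except (NoContrastError, ValueError) as exc:
                logger.warning("eQTL skipped for %s: %s", gene, exc)
        if config.run_survival:
            times = [p.dss_time for p in patients]
            events = [p.dss_event for p in patients]
            groups = ["mutated" if status[p.patient_id] else "wildtype" for p in patients]
            try:
                survival_results.append(
                    association.km_by_status(
                        times, events, groups, gene=gene,
                        alteration_type=region.alteration_type,
                    )
                )
            except ValueError as exc:
                logger.warning("KM skipped for %s: %s", gene, exc)
            try:
                survival_results.append(
                    association.cox_expression(
                        times, events, expr.to_numpy(), gene=gene,
                        alteration_type=region.alteration_type,
                    )
                )
            except (NoContrastError, ValueError, RuntimeError) as exc:
                logger.warning("Cox skipped for %s: %s", gene, exc)
    association.adjust_bh(eqtl_results)
    counts["eqtl.genes_tested"] = len(eqtl_results)
    counts["survival.analyses"] = len(survival_results)

    _write_outputs(
        out_dir, counts, specific, validated, matrices, eqtl_results, survival_results
    )
    return PipelineResult(
        counts=counts,
        validated_regions=validated,
        young_specific={
            label: [r for t in (GAIN, LOSS) for r in specific[label][t]]
            for label in specific
        },
        mutation_matrices=matrices,
        eqtl_results=eqtl_results,
        survival_results=survival_results,
        out_dir=out_dir,
    )


def _write_outputs(
    out_dir: Path,
    counts: dict,
    specific: dict,
    validated: Sequence[RecurrentRegion],
    matrices: dict[str, MutationMatrix],
    eqtl_results: Sequence[EqtlResult],
    survival_results: Sequence[SurvivalResult],
) -> None:
    for label, by_type in specific.items():
        for alt_type, regions in by_type.items():
            recurrent_caller.write_region_table(
                regions, out_dir / f"young_specific_{label}_{alt_type}.tsv"
            )
    for alt_type in (GAIN, LOSS):
        recurrent_caller.write_region_table(
            [r for r in validated if r.alteration_type == alt_type],
            out_dir / f"validated_{alt_type}.tsv",
        )
    recurrent_caller.write_region_bed(validated, out_dir / "validated_inner.bed")
    for label, matrix in matrices.items():
        matrix.to_tsv(out_dir / f"mutation_matrix_{label}.tsv")
    association.eqtl_table(eqtl_results, out_dir / "eqtl.tsv")
    association.survival_table(survival_results, out_dir / "survival.tsv")
    with open(out_dir / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    logger.info("pipeline outputs written to %s", out_dir)
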