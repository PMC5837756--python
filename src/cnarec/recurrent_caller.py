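"""Recurrent CNA regions: clique filtering, age-group specificity and
discovery/validation matching.

A recurrent region is a surviving maximal clique of same-type patient
segments: the inner coordinates are the minimal common region (MCR)
shared by every carrier, the outer coordinates the union extent.  Regions
kept must have clique size >= 2, >= 5 distinct patients and an MCR of at
least 1 kb (all configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .interval_clique import clique_mcr, clique_outer, sweep_maximal_cliques
from .segment_io import (
    CNASegment,
    GenomicInterval,
    chrom_sort_key,
    region_size,
)

__all__ = [
    "RecurrentRegion",
    "call_recurrent_regions",
    "group_specific_regions",
    "match_discovery_validation",
    "write_region_table",
    "read_region_table",
    "write_region_bed",
    "SPECIFICITY_POLICIES",
]

REGION_TABLE_COLUMNS = [
    "Chr",
    "InnerStart",
    "InnerEnd",
    "InnerSize",
    "OuterStart",
    "OuterEnd",
    "OuterSize",
    "GeneSymbols",
    "Size1",
    "Size2",
]


@dataclass(frozen=True)
class RecurrentRegion:
    """One recurrent CNA region (a filtered maximal clique)."""

    chrom: str
    alteration_type: str
    inner: GenomicInterval
    outer: GenomicInterval
    patient_set: frozenset[str]
    cohort: str = "discovery"
    size1: int | None = None
    size2: int | None = None
    genes: tuple[str, ...] = ()
    genome_class: str | None = None  # "coding" / "non-coding" once annotated

    def __post_init__(self) -> None:
        if not self.outer.contains(self.inner):
            raise ValueError("inner MCR must be contained in the outer span")

    @property
    def n_patients(self) -> int:
        return len(self.patient_set)

    @property
    def inner_size(self) -> int:
        return region_size(self.inner)

    @property
    def outer_size(self) -> int:
        return region_size(self.outer)

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.inner.start, self.inner.end)


def call_recurrent_regions(
    segments: Iterable[CNASegment],
    min_clique: int = 2,
    min_patients: int = 5,
    min_mcr_size: int = 1000,
    cohort: str = "discovery",
) -> list[RecurrentRegion]:
    """Enumerate maximal cliques per chromosome and keep recurrent ones.

    Input segments must all be of one alteration type (one age group,
    gains and losses are analysed separately).  Filters are applied in
    order: clique size >= min_clique, distinct patients >= min_patients,
    MCR size >= min_mcr_size.
    """
    segments = list(segments)
    if not segments:
        return []
    types = {s.alteration_type for s in segments}
    if len(types) > 1:
        raise ValueError(f"mixed alteration types in one calling run: {sorted(types)}")
    alteration_type = types.pop()

    by_chrom: dict[str, list[CNASegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    regions: list[RecurrentRegion] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        for clique in sweep_maximal_cliques(by_chrom[chrom]):
            if len(clique) < min_clique:
                continue
            if len(clique.patient_set) < min_patients:
                continue
            mcr = clique_mcr(clique)
            if mcr.size < min_mcr_size:
                continue
            regions.append(
                RecurrentRegion(
                    chrom=chrom,
                    alteration_type=alteration_type,
                    inner=mcr,
                    outer=clique_outer(clique),
                    patient_set=clique.patient_set,
                    cohort=cohort,
                )
            )
    regions.sort(key=RecurrentRegion.sort_key)
    return regions


def _any_overlap(target: RecurrentRegion, other: RecurrentRegion) -> bool:
    return target.inner.overlaps(other.inner)


def _reciprocal_50(target: RecurrentRegion, other: RecurrentRegion) -> bool:
    ov = target.inner.overlap_bp(other.inner)
    return ov >= 0.5 * target.inner_size and ov >= 0.5 * other.inner_size


SPECIFICITY_POLICIES = {
    "any-overlap": _any_overlap,
    "reciprocal-50": _reciprocal_50,
}


def group_specific_regions(
    target_regions: Sequence[RecurrentRegion],
    other_regions: Sequence[RecurrentRegion],
    policy: str = "any-overlap",
) -> list[RecurrentRegion]:
    """Regions of the target group whose inner MCR does not overlap (under
    the chosen policy) any same-type region of the other group."""
    try:
        hits = SPECIFICITY_POLICIES[policy]
    except KeyError:
        raise ValueError(
            f"unknown specificity policy {policy!r}; "
            f"choose from {sorted(SPECIFICITY_POLICIES)}"
        ) from None
    kept = []
    for region in target_regions:
        clash = any(
            other.alteration_type == region.alteration_type and hits(region, other)
            for other in other_regions
        )
        if not clash:
            kept.append(region)
    return kept


def match_discovery_validation(
    discovery_regions: Sequence[RecurrentRegion],
    validation_regions: Sequence[RecurrentRegion],
) -> list[RecurrentRegion]:
    """Keep discovery regions whose inner MCR overlaps >= 1 same-type
    validation region's inner MCR.

    The validated record carries the discovery coordinates; size1 is the
    discovery patient count and size2 the patient count of the
    best-overlapping validation partner (ties: larger overlap, then
    leftmost validation start).
    """
    validated = []
    for region in discovery_regions:
        best = None
        best_key = None
        for cand in validation_regions:
            if cand.alteration_type != region.alteration_type:
                continue
            ov = region.inner.overlap_bp(cand.inner)
            if ov <= 0:
                continue
            key = (-ov, cand.inner.start)
            if best is None or key < best_key:
                best, best_key = cand, key
        if best is not None:
            validated.append(
                replace(
                    region,
                    cohort="validated",
                    size1=region.n_patients,
                    size2=best.n_patients,
                )
            )
    validated.sort(key=RecurrentRegion.sort_key)
    return validated


def write_region_table(
    regions: Sequence[RecurrentRegion], path: str | Path
) -> None:
    """Tab-separated region table (Chr .. GeneSymbols, Size1, Size2)."""
    rows = []
    for r in sorted(regions, key=RecurrentRegion.sort_key):
        rows.append(
            {
                "Chr": r.chrom,
                "InnerStart": r.inner.start,
                "InnerEnd": r.inner.end,
                "InnerSize": r.inner_size,
                "OuterStart": r.outer.start,
                "OuterEnd": r.outer.end,
                "OuterSize": r.outer_size,
                "GeneSymbols": "; ".join(r.genes),
                "Size1": r.size1 if r.size1 is not None else r.n_patients,
                "Size2": r.size2 if r.size2 is not None else "",
                "Type": r.alteration_type,
                "Patients": ",".join(sorted(r.patient_set)),
            }
        )
    cols = REGION_TABLE_COLUMNS + ["Type", "Patients"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> list[RecurrentRegion]:
    """Inverse of :func:`write_region_table` (extra columns included)."""
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str, "GeneSymbols": str})
    regions = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        genes_raw = rec.get("GeneSymbols", "")
        genes = (
            tuple(g.strip() for g in str(genes_raw).split(";") if g.strip())
            if isinstance(genes_raw, str) and genes_raw.strip()
            else ()
        )
        patients_raw = rec.get("Patients", "")
        patients = (
            frozenset(str(patients_raw).split(","))
            if isinstance(patients_raw, str) and patients_raw
            else frozenset()
        )
        size2 = rec.get("Size2")
        size2 = None if pd.isna(size2) or size2 == "" else int(size2)
        regions.append(
            RecurrentRegion(
                chrom=str(rec["Chr"]),
                alteration_type=str(rec["Type"]),
                inner=GenomicInterval(str(rec["Chr"]), int(rec["InnerStart"]), int(rec["InnerEnd"])),
                outer=GenomicInterval(str(rec["Chr"]), int(rec["OuterStart"]), int(rec["OuterEnd"])),
                patient_set=patients,
                cohort="validated" if size2 is not None else "discovery",
                size1=int(rec["Size1"]) if not pd.isna(rec.get("Size1")) else None,
                size2=size2,
                genes=genes,
            )
        )
    return regions


def write_region_bed(regions: Sequence[RecurrentRegion], path: str | Path) -> None:
    """BED export of inner MCRs; the name field carries type and gene symbols."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=RecurrentRegion.sort_key):
            name = r.alteration_type
            if r.genes:
                name += ":" + "|".join(r.genes)
            fh.write(f"{r.chrom}\t{r.inner.start}\t{r.inner.end}\t{name}\n")
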