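"""Gene models, region annotation and the gene x patient mutation matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .recurrent_caller import RecurrentRegion
from .segment_io import CNASegment, GenomicInterval, PatientRecord

__all__ = [
    "GeneModel",
    "MutationMatrix",
    "load_gene_models",
    "write_gene_models_bed",
    "annotate_regions",
    "carrier_status",
    "build_mutation_matrix",
]


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    span: GenomicInterval
    strand: str = "+"
    exons: tuple[GenomicInterval, ...] = ()
    is_protein_coding: bool = True

    def __post_init__(self) -> None:
        for exon in self.exons:
            if not self.span.contains(exon):
                raise ValueError(
                    f"exon {exon} of gene {self.symbol} lies outside its span {self.span}"
                )


class GeneModelError(ValueError):
    """Unparseable gene-model file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _normalize_chrom(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


_NONCODING_BIOTYPES = {
    "lincRNA", "lncRNA", "miRNA", "snoRNA", "snRNA", "rRNA", "tRNA",
    "pseudogene", "processed_pseudogene", "unprocessed_pseudogene",
    "antisense", "misc_RNA",
}


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _load_bed(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GeneModelError(
                    f"BED gene models need >= 4 columns, got {len(fields)}", lineno
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GeneModelError(f"non-integer coordinates in {line!r}", lineno)
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            try:
                span = GenomicInterval(_normalize_chrom(fields[0]), start, end)
            except ValueError as exc:
                raise GeneModelError(str(exc), lineno)
            models.append(GeneModel(symbol=fields[3], chrom=span.chrom, span=span, strand=strand))
    return models


def _load_gtf(path: Path) -> list[GeneModel]:
    # GTF is 1-based fully closed; converted to half-open on load.
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GeneModelError(
                    f"GTF records need 9 columns, got {len(fields)}", lineno
                )
            feature = fields[2]
            if feature not in ("gene", "exon"):
                continue
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError:
                raise GeneModelError(f"non-integer coordinates in {line!r}", lineno)
            attrs = _parse_gtf_attributes(fields[8])
            symbol = attrs.get("gene_name") or attrs.get("gene_id")
            if not symbol:
                raise GeneModelError("record lacks gene_name/gene_id", lineno)
            chrom = _normalize_chrom(fields[0])
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise GeneModelError(str(exc), lineno)
            entry = genes.setdefault(
                symbol,
                {"chrom": chrom, "span": None, "strand": fields[6], "exons": [],
                 "biotype": attrs.get("gene_biotype") or attrs.get("gene_type")},
            )
            if feature == "gene":
                entry["span"] = iv
                entry["strand"] = fields[6]
            else:
                entry["exons"].append(iv)
    models = []
    for symbol, entry in genes.items():
        span = entry["span"]
        exons = tuple(sorted(entry["exons"], key=lambda e: e.start))
        if span is None:  # exon-only GTF: span is the exon extent
            span = GenomicInterval(
                entry["chrom"],
                min(e.start for e in exons),
                max(e.end for e in exons),
            )
        coding = entry["biotype"] is None or entry["biotype"] not in _NONCODING_BIOTYPES
        models.append(
            GeneModel(
                symbol=symbol,
                chrom=entry["chrom"],
                span=span,
                strand=entry["strand"] if entry["strand"] in "+-" else "+",
                exons=exons,
                is_protein_coding=coding,
            )
        )
    return models


def _dedupe(models: list[GeneModel]) -> list[GeneModel]:
    by_key: dict[tuple[str, str], GeneModel] = {}
    for model in models:
        key = (model.symbol, model.chrom)
        prev = by_key.get(key)
        if prev is None:
            by_key[key] = model
        else:
            warnings.warn(
                f"duplicate gene symbol {model.symbol} on chrom {model.chrom}; "
                "keeping the widest span",
                stacklevel=3,
            )
            if model.span.size > prev.span.size:
                by_key[key] = model
    return list(by_key.values())


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED (0-based half-open) or GTF (1-based closed,
    converted); duplicate symbols on one chromosome keep the widest span."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".bed",):
        models = _load_bed(path)
    elif suffix in (".gtf", ".gff"):
        models = _load_gtf(path)
    else:
        raise GeneModelError(f"unrecognized gene-model format: {path.name}")
    return _dedupe(models)


def write_gene_models_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.chrom}\t{m.span.start}\t{m.span.end}\t{m.symbol}\t0\t{m.strand}\n"
            )


def annotate_regions(
    regions: Sequence[RecurrentRegion],
    genes: Sequence[GeneModel],
    use_outer: bool = False,
) -> list[RecurrentRegion]:
    """Attach gene symbols and a coding/non-coding class to each region.

    A gene is assigned when its span overlaps the region's inner MCR (or
    outer span when ``use_outer``).  The region is "coding" if it overlaps
    at least one protein-coding gene; when that gene carries exon models,
    an exon must overlap, otherwise the whole span counts.
    """
    annotated = []
    for region in regions:
        target = region.outer if use_outer else region.inner
        symbols = []
        coding = False
        for gene in genes:
            if not gene.span.overlaps(target):
                continue
            symbols.append(gene.symbol)
            if gene.is_protein_coding:
                if gene.exons:
                    coding = coding or any(e.overlaps(target) for e in gene.exons)
                else:
                    coding = True
        annotated.append(
            replace(
                region,
                genes=tuple(sorted(symbols)),
                genome_class="coding" if coding else "non-coding",
            )
        )
    return annotated


def carrier_status(
    region: RecurrentRegion,
    segments: Iterable[CNASegment],
    patients: Sequence[PatientRecord],
) -> pd.Series:
    """Boolean per-patient CNA status for one region.

    A patient is a carrier iff they have >= 1 (filtered) segment of the
    region's alteration type overlapping the region's inner MCR; this is
    recomputable identically in any cohort.
    """
    carriers = {
        seg.patient_id
        for seg in segments
        if seg.alteration_type == region.alteration_type
        and seg.interval.overlaps(region.inner)
    }
    ids = [p.patient_id for p in patients]
    return pd.Series([pid in carriers for pid in ids], index=ids, dtype=bool)


@dataclass
class MutationMatrix:
    """Gene x patient alteration states, rows ordered by mutation frequency."""

    states: pd.DataFrame  # values in {"gain", "loss", "none"}
    gene_types: Mapping[str, str]  # gene symbol -> defining region type

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def patients(self) -> list[str]:
        return list(self.states.columns)

    def frequency(self, gene: str) -> float:
        row = self.states.loc[gene]
        return float((row != "none").mean())

    def to_tsv(self, path: str | Path) -> None:
        symbols = {"gain": "G", "loss": "L", "none": "."}
        out = self.states.replace(symbols)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def build_mutation_matrix(
    regions: Sequence[RecurrentRegion],
    segments: Iterable[CNASegment],
    patients: Sequence[PatientRecord],
) -> MutationMatrix:
    """Gene x patient matrix of {gain, loss, none} states.

    Each annotated region contributes its genes; a (gene, patient) cell is
    the defining region's type iff the patient carries a matching segment
    overlapping that region's inner MCR.  A gene keeps the type of the
    region that defined it (gain-region genes never report losses).  Rows
    are sorted by descending alteration frequency, ties alphabetically.
    """
    segments = list(segments)
    ids = [p.patient_id for p in patients]
    gene_types: dict[str, str] = {}
    rows: dict[str, pd.Series] = {}
    for region in regions:
        if not region.genes:
            continue
        status = carrier_status(region, segments, patients)
        for gene in region.genes:
            if gene in gene_types and gene_types[gene] != region.alteration_type:
                warnings.warn(
                    f"gene {gene} appears in both gain and loss regions; "
                    f"keeping the first ({gene_types[gene]})",
                    stacklevel=2,
                )
                continue
            gene_types.setdefault(gene, region.alteration_type)
            cell = pd.Series("none", index=ids, dtype=object)
            cell[status] = region.alteration_type
            if gene in rows:  # same gene from several same-type regions: union
                prior = rows[gene]
                cell[prior != "none"] = gene_types[gene]
            rows[gene] = cell

    if rows:
        df = pd.DataFrame(rows).T
        df = df[ids]
        freq = (df != "none").mean(axis=1)
        order = sorted(df.index, key=lambda g: (-freq[g], g))
        df = df.loc[order]
    else:
        df = pd.DataFrame(index=pd.Index([], name="gene"), columns=ids, dtype=object)
    return MutationMatrix(states=df, gene_types=gene_types)
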