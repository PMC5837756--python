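"""Reading, validation, filtering and cohort partitioning of CNA segment calls.

Segment calls arrive in a SEG-like tab-separated dialect (one row per
patient-level copy-number segment, as produced by circular binary
segmentation).  Coordinates are held internally as half-open
``[start, end)`` spans so that ``size == end - start``; published region
tables in this field print coordinates consistent with that arithmetic,
and a dialect option handles 1-based fully-closed inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "CNASegment",
    "PatientRecord",
    "SegDialect",
    "SegmentIOError",
    "SegmentRowError",
    "GAIN",
    "LOSS",
    "NEUTRAL",
    "YOUNG",
    "OLD",
    "region_size",
    "jaccard",
    "read_segments",
    "write_segments",
    "read_clinical",
    "write_clinical",
    "filter_segments",
    "partition_cohort",
    "CHROM_ORDER",
    "chrom_sort_key",
]

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

YOUNG = "young"
OLD = "old"

#: Karyotype ordering used for every sorted output table.
CHROM_ORDER = [str(c) for c in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing 1..22 before X/Y and unknown labels last."""
    return (_CHROM_RANK.get(chrom, len(CHROM_ORDER)), chrom)


class SegmentIOError(ValueError):
    """File-level problem (missing column, unknown format)."""


class SegmentRowError(SegmentIOError):
    """A single input row violates an invariant; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval [{self.start}, {self.end}) on chrom {self.chrom}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap; intervals that merely touch do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def region_size(interval: GenomicInterval) -> int:
    """Size in base pairs of a half-open interval (``end - start``)."""
    return interval.size


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Jaccard overlap |a ∩ b| / |a ∪ b| of two intervals (0 if different chroms)."""
    inter = a.overlap_bp(b)
    if inter == 0:
        return 0.0
    union = a.size + b.size - inter
    return inter / union


def _alteration_type(cn_state: int) -> str:
    if cn_state > 2:
        return GAIN
    if cn_state < 2:
        return LOSS
    return NEUTRAL


@dataclass(frozen=True)
class CNASegment:
    """One patient-level CNA call: interval + probe support + copy-number state."""

    patient_id: str
    interval: GenomicInterval
    n_probes: int
    cn_state: int

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError(f"n_probes must be positive, got {self.n_probes}")

    @property
    def alteration_type(self) -> str:
        """gain if cn_state > 2, loss if cn_state < 2, else neutral."""
        return _alteration_type(self.cn_state)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def size(self) -> int:
        return self.interval.size


@dataclass(frozen=True)
class PatientRecord:
    """Clinical record: age, disease-specific survival and optional covariates."""

    patient_id: str
    age: float
    dss_time: float
    dss_event: int
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dss_time < 0:
            raise ValueError(f"dss_time must be >= 0, got {self.dss_time}")
        if self.dss_event not in (0, 1):
            raise ValueError(f"dss_event must be 0 or 1, got {self.dss_event}")

    def age_group(self, young_cutoff: float = 45.0) -> str:
        """young iff age < cutoff; the boundary age itself is old."""
        return YOUNG if self.age < young_cutoff else OLD


@dataclass(frozen=True)
class SegDialect:
    """Column mapping and coordinate conventions of a SEG-like file.

    ``coords`` is either ``"half-open"`` (coordinates used as-is, size =
    end - start) or ``"one-based-inclusive"`` (start decremented on load,
    size = end - start + 1).  ``cn_encoding`` is ``"absolute"`` (2 =
    neutral) or ``"relative"`` ({-2..2}-style codes, 0 = neutral, mapped
    onto absolute states by adding 2).
    """

    patient: str = "ID"
    chrom: str = "chrom"
    start: str = "loc.start"
    end: str = "loc.end"
    n_probes: str = "num.mark"
    cn_state: str = "cn.state"
    coords: str = "half-open"
    cn_encoding: str = "absolute"

    def columns(self) -> list[str]:
        return [self.patient, self.chrom, self.start, self.end, self.n_probes, self.cn_state]


DEFAULT_DIALECT = SegDialect()


def _normalize_chrom(label: str) -> str:
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def _coerce_int(value, what: str, line: int):
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SegmentRowError(f"non-numeric {what}: {value!r}", line)
    if f != int(f):
        raise SegmentRowError(f"non-integer {what}: {value!r}", line)
    return int(f)


def read_segments(
    path: str | Path,
    dialect: SegDialect = DEFAULT_DIALECT,
) -> list[CNASegment]:
    """Load patient-level CNA segments from a SEG-like tab-separated file.

    Neutral segments are retained (tagged by ``alteration_type``);
    they are removed later by :func:`filter_segments`.  Overlapping
    same-patient same-chromosome segments trigger a warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise SegmentIOError(f"segment file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in dialect.columns():
        if col not in df.columns:
            raise SegmentIOError(f"missing required column {col!r} in {path}")

    segments: list[CNASegment] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after the header
        rec = dict(zip(df.columns, row))
        start = _coerce_int(rec[dialect.start], "start coordinate", line)
        end = _coerce_int(rec[dialect.end], "end coordinate", line)
        if dialect.coords == "one-based-inclusive":
            start -= 1
        elif dialect.coords != "half-open":
            raise SegmentIOError(f"unknown coordinate convention {dialect.coords!r}")
        if end <= start:
            raise SegmentRowError(f"end ({end}) <= start ({start})", line)
        n_probes = _coerce_int(rec[dialect.n_probes], "probe count", line)
        if n_probes < 1:
            raise SegmentRowError(f"probe count must be positive, got {n_probes}", line)
        cn = _coerce_int(rec[dialect.cn_state], "copy-number state", line)
        if dialect.cn_encoding == "relative":
            cn = max(0, cn + 2)
        elif dialect.cn_encoding != "absolute":
            raise SegmentIOError(f"unknown cn encoding {dialect.cn_encoding!r}")
        segments.append(
            CNASegment(
                patient_id=str(rec[dialect.patient]),
                interval=GenomicInterval(_normalize_chrom(rec[dialect.chrom]), start, end),
                n_probes=n_probes,
                cn_state=cn,
            )
        )
    _warn_on_patient_overlaps(segments)
    return segments


def _warn_on_patient_overlaps(segments: Sequence[CNASegment]) -> None:
    by_key: dict[tuple[str, str], list[CNASegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.patient_id, seg.chrom), []).append(seg)
    for (pid, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.interval.start)
        for prev, cur in zip(group, group[1:]):
            if prev.interval.overlaps(cur.interval):
                warnings.warn(
                    f"overlapping segments for patient {pid} on chrom {chrom}: "
                    f"[{prev.interval.start},{prev.interval.end}) and "
                    f"[{cur.interval.start},{cur.interval.end})",
                    stacklevel=3,
                )


def write_segments(
    segments: Iterable[CNASegment],
    path: str | Path,
    dialect: SegDialect = DEFAULT_DIALECT,
) -> None:
    """Write segments back to the SEG dialect (inverse of :func:`read_segments`)."""
    rows = []
    for seg in segments:
        start = seg.interval.start
        if dialect.coords == "one-based-inclusive":
            start += 1
        cn = seg.cn_state
        if dialect.cn_encoding == "relative":
            cn = cn - 2
        rows.append(
            {
                dialect.patient: seg.patient_id,
                dialect.chrom: seg.chrom,
                dialect.start: start,
                dialect.end: seg.interval.end,
                dialect.n_probes: seg.n_probes,
                dialect.cn_state: cn,
            }
        )
    pd.DataFrame(rows, columns=dialect.columns()).to_csv(path, sep="\t", index=False)


_CLINICAL_REQUIRED = ["patient_id", "age", "dss_time", "dss_event"]


def read_clinical(path: str | Path) -> list[PatientRecord]:
    """Load the clinical table (patient_id, age, dss_time, dss_event, extras)."""
    path = Path(path)
    if not path.exists():
        raise SegmentIOError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _CLINICAL_REQUIRED:
        if col not in df.columns:
            raise SegmentIOError(f"missing required column {col!r} in {path}")
    extra = [c for c in df.columns if c not in _CLINICAL_REQUIRED]
    records = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        records.append(
            PatientRecord(
                patient_id=str(rec["patient_id"]),
                age=float(rec["age"]),
                dss_time=float(rec["dss_time"]),
                dss_event=int(rec["dss_event"]),
                covariates={c: str(rec[c]) for c in extra},
            )
        )
    return records


def write_clinical(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "age": p.age,
            "dss_time": p.dss_time,
            "dss_event": p.dss_event,
        }
        row.update(p.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_segments(
    segments: Iterable[CNASegment],
    min_probes: int = 10,
    min_size: int = 1000,
) -> list[CNASegment]:
    """Keep non-neutral segments supported by >= min_probes probes and
    spanning >= min_size bp."""
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    return [
        seg
        for seg in segments
        if seg.alteration_type != NEUTRAL
        and seg.n_probes >= min_probes
        and seg.size >= min_size
    ]


def partition_cohort(
    segments: Iterable[CNASegment],
    patients: Iterable[PatientRecord],
    young_cutoff: float = 45.0,
) -> dict[tuple[str, str], list[CNASegment]]:
    """Split segments into the four (age group x alteration type) buckets.

    Returns a dict keyed by ``(group, type)`` covering exactly
    {young, old} x {gain, loss}.  Neutral segments are rejected (filter
    first).  Segments whose patient is absent from the clinical table
    raise an error listing every orphan id.
    """
    by_patient = {p.patient_id: p for p in patients}
    buckets: dict[tuple[str, str], list[CNASegment]] = {
        (g, t): [] for g in (YOUNG, OLD) for t in (GAIN, LOSS)
    }
    orphans: set[str] = set()
    for seg in segments:
        if seg.alteration_type == NEUTRAL:
            raise ValueError(
                "neutral segment passed to partition_cohort; run filter_segments first"
            )
        rec = by_patient.get(seg.patient_id)
        if rec is None:
            orphans.add(seg.patient_id)
            continue
        buckets[(rec.age_group(young_cutoff), seg.alteration_type)].append(seg)
    if orphans:
        raise SegmentIOError(
            "segments reference patients absent from the clinical table: "
            + ", ".join(sorted(orphans))
        )
    return buckets
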