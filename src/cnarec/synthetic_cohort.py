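"""Synthetic paired tumour cohorts with planted recurrent CNA structure.

Generates everything the pipeline consumes — SEG-style segment calls,
a clinical table with disease-specific survival, an expression matrix and
BED gene models — for two age groups and a paired discovery/validation
design.  Planted regions have configurable penetrance, breakpoint jitter,
expression effects and survival hazards; background noise segments are
drawn independently of age group.  All randomness flows from one master
seed through spawned generator streams, so cohorts are reproducible and
independently regenerable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_annotation import GeneModel, write_gene_models_bed
from .segment_io import (
    CNASegment,
    GAIN,
    GenomicInterval,
    LOSS,
    PatientRecord,
    SegDialect,
    write_clinical,
    write_segments,
)

__all__ = [
    "PlantedRegion",
    "SimConfig",
    "CohortBundle",
    "simulate_cohort",
    "simulate_paired_experiment",
    "default_chrom_lengths",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


#: Approximate GRCh37 chromosome lengths (bp), autosomes + X.
_GRCH37_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}


def default_chrom_lengths() -> dict[str, int]:
    return dict(_GRCH37_LENGTHS)


@dataclass(frozen=True)
class PlantedRegion:
    """One recurrent CNA to plant, with its expression/survival coupling."""

    chrom: str
    start: int
    end: int
    alteration_type: str  # gain / loss
    target_group: str = "young"  # young / old / both
    penetrance: float = 0.4
    jitter_sd: float = 300.0  # bp, Gaussian jitter on each breakpoint
    gene_symbol: str | None = None
    expression_baseline: float = 8.0
    expression_beta: float = 0.0  # carrier effect, in units of noise SD
    expression_sd: float = 1.0
    survival_log_hazard: float = 0.0  # gamma on carrier status

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def symbol(self, index: int) -> str:
        return self.gene_symbol or f"G{index:03d}_{self.chrom}_{self.alteration_type.upper()}"


@dataclass
class SimConfig:
    """Full specification of a synthetic paired-cohort experiment."""

    planted_regions: list[PlantedRegion] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)
    n_young: int = 120
    n_old: int = 300
    noise_rate: float = 0.2  # Poisson mean background segments per patient
    noise_size_range: tuple[int, int] = (1_000, 5_000_000)  # log-uniform
    probes_per_kb: float = 15.0
    gain_cn: int = 3
    loss_cn: int = 1
    baseline_hazard: float = 0.05  # events per year
    hazard_on: str = "carrier"  # or "expression"
    censor_time: float = 15.0  # years, administrative censoring
    young_age_range: tuple[float, float] = (25.0, 44.9)
    old_age_range: tuple[float, float] = (45.0, 75.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_young < 0 or self.n_old < 0:
            raise ConfigError("cohort sizes must be non-negative")
        for region in self.planted_regions:
            if not 0.0 <= region.penetrance <= 1.0:
                raise ConfigError(
                    f"penetrance {region.penetrance} of region on chrom "
                    f"{region.chrom} outside [0, 1]"
                )
            if region.alteration_type not in (GAIN, LOSS):
                raise ConfigError(f"unknown alteration type {region.alteration_type!r}")
            if region.target_group not in ("young", "old", "both"):
                raise ConfigError(f"unknown target group {region.target_group!r}")
            length = self.chrom_lengths.get(region.chrom)
            if length is None:
                raise ConfigError(f"planted region on unknown chromosome {region.chrom}")
            if not (0 <= region.start < region.end <= length):
                raise ConfigError(
                    f"planted region [{region.start}, {region.end}) outside "
                    f"chromosome {region.chrom} (length {length})"
                )
        if self.hazard_on not in ("carrier", "expression"):
            raise ConfigError(f"hazard_on must be 'carrier' or 'expression'")


@dataclass
class CohortBundle:
    """Everything simulated for one cohort."""

    label: str
    segments: list[CNASegment]
    patients: list[PatientRecord]
    expression: pd.DataFrame  # genes x patients
    gene_models: list[GeneModel]
    carriers: pd.DataFrame  # genes x patients, bool truth of planted status
    manifest: dict

    def write(self, out_dir: str | Path, dialect: SegDialect = SegDialect()) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_segments(self.segments, out / "segments.seg", dialect)
        write_clinical(self.patients, out / "clinical.tsv")
        exp = self.expression.copy()
        exp.index.name = "gene"
        exp.to_csv(out / "expression.tsv", sep="\t")
        write_gene_models_bed(self.gene_models, out / "genes.bed")
        carriers = self.carriers.astype(int)
        carriers.index.name = "gene"
        carriers.to_csv(out / "carriers.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


_COHORT_INDEX = {"discovery": 0, "validation": 1}


def _cohort_rng(config: SimConfig, label: str) -> np.random.Generator:
    index = _COHORT_INDEX.get(label)
    if index is None:  # ad-hoc labels still deterministic
        index = 10 + (abs(hash(label)) % 1000)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    return np.random.default_rng(ss)


def _jittered_segment(
    region: PlantedRegion,
    pid: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> CNASegment:
    length = config.chrom_lengths[region.chrom]
    start = region.start + int(round(rng.normal(0.0, region.jitter_sd))) if region.jitter_sd > 0 else region.start
    end = region.end + int(round(rng.normal(0.0, region.jitter_sd))) if region.jitter_sd > 0 else region.end
    start = max(0, min(start, length - 2))
    end = max(start + 1, min(end, length))
    iv = GenomicInterval(region.chrom, start, end)
    cn = config.gain_cn if region.alteration_type == GAIN else config.loss_cn
    n_probes = _probe_count(iv.size, config, rng)
    return CNASegment(patient_id=pid, interval=iv, n_probes=n_probes, cn_state=cn)


def _probe_count(size: int, config: SimConfig, rng: np.random.Generator) -> int:
    lam = max(config.probes_per_kb * size / 1000.0, 1.0)
    return max(1, int(rng.poisson(lam)))


def _noise_segments(
    pid: str, config: SimConfig, rng: np.random.Generator
) -> list[CNASegment]:
    k = int(rng.poisson(config.noise_rate))
    if k == 0:
        return []
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    lo, hi = config.noise_size_range
    out = []
    for _ in range(k):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        clen = config.chrom_lengths[chrom]
        size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        size = min(size, clen - 1)
        start = int(rng.integers(0, clen - size))
        iv = GenomicInterval(chrom, start, start + size)
        cn = config.gain_cn if rng.random() < 0.5 else config.loss_cn
        out.append(
            CNASegment(
                patient_id=pid,
                interval=iv,
                n_probes=_probe_count(iv.size, config, rng),
                cn_state=cn,
            )
        )
    return out


def simulate_cohort(config: SimConfig, label: str = "discovery") -> CohortBundle:
    """Simulate one cohort (segments, clinical, expression, gene models).

    Deterministic given ``config.seed`` and ``label``; the two standard
    labels (discovery, validation) draw from independent spawned streams.
    """
    config.validate()
    rng = _cohort_rng(config, label)
    prefix = label[:4].upper()

    groups = ["young"] * config.n_young + ["old"] * config.n_old
    pids = [f"{prefix}_{i:04d}" for i in range(len(groups))]
    ages = []
    for group in groups:
        lo, hi = config.young_age_range if group == "young" else config.old_age_range
        ages.append(float(rng.uniform(lo, hi)))

    gene_symbols = [r.symbol(i) for i, r in enumerate(config.planted_regions)]
    carriers = pd.DataFrame(
        False, index=gene_symbols, columns=pids, dtype=bool
    )

    segments: list[CNASegment] = []
    for region, symbol in zip(config.planted_regions, gene_symbols):
        for pid, group in zip(pids, groups):
            if region.target_group != "both" and region.target_group != group:
                continue
            if rng.random() < region.penetrance:
                carriers.loc[symbol, pid] = True
                segments.append(_jittered_segment(region, pid, config, rng))
    for pid in pids:
        segments.extend(_noise_segments(pid, config, rng))

    # Expression: baseline + beta * carrier + Gaussian noise, per planted gene.
    expr = np.empty((len(gene_symbols), len(pids)))
    for gi, (region, symbol) in enumerate(zip(config.planted_regions, gene_symbols)):
        carrier = carriers.loc[symbol].to_numpy()
        noise = rng.normal(0.0, region.expression_sd, size=len(pids))
        expr[gi] = (
            region.expression_baseline
            + region.expression_beta * region.expression_sd * carrier
            + noise
        )
    expression = pd.DataFrame(expr, index=gene_symbols, columns=pids)

    # Survival: exponential times under log-linear hazards, administrative
    # censoring at the configured window.
    log_hazard = np.full(len(pids), math.log(config.baseline_hazard))
    for region, symbol in zip(config.planted_regions, gene_symbols):
        if region.survival_log_hazard == 0.0:
            continue
        if config.hazard_on == "carrier":
            covariate = carriers.loc[symbol].to_numpy().astype(float)
        else:
            values = expression.loc[symbol].to_numpy()
            covariate = (values - values.mean()) / values.std(ddof=1)
        log_hazard = log_hazard + region.survival_log_hazard * covariate
    raw_times = rng.exponential(scale=1.0 / np.exp(log_hazard))
    dss_time = np.minimum(raw_times, config.censor_time)
    dss_event = (raw_times <= config.censor_time).astype(int)

    patients = [
        PatientRecord(
            patient_id=pid,
            age=age,
            dss_time=float(t),
            dss_event=int(e),
            covariates={"cohort": label},
        )
        for pid, age, t, e in zip(pids, ages, dss_time, dss_event)
    ]

    gene_models = [
        GeneModel(
            symbol=symbol,
            chrom=region.chrom,
            span=region.interval(),
            strand="+",
            is_protein_coding=True,
        )
        for region, symbol in zip(config.planted_regions, gene_symbols)
    ]

    manifest = {
        "label": label,
        "seed": config.seed,
        "n_young": config.n_young,
        "n_old": config.n_old,
        "n_segments": len(segments),
        "planted_regions": [asdict(r) for r in config.planted_regions],
        "noise_rate": config.noise_rate,
    }
    return CohortBundle(
        label=label,
        segments=segments,
        patients=patients,
        expression=expression,
        gene_models=gene_models,
        carriers=carriers,
        manifest=manifest,
    )


def simulate_paired_experiment(
    config: SimConfig,
) -> tuple[CohortBundle, CohortBundle]:
    """Independent discovery and validation cohorts sharing one configuration
    (and hence the same planted regions)."""
    return simulate_cohort(config, "discovery"), simulate_cohort(config, "validation")
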