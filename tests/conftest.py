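import numpy as np
import pytest

from cnarec.segment_io import CNASegment, GenomicInterval, PatientRecord
from cnarec.synthetic_cohort import PlantedRegion, SimConfig


def seg(pid, chrom, start, end, n_probes=20, cn=3):
    return CNASegment(
        patient_id=pid,
        interval=GenomicInterval(chrom, start, end),
        n_probes=n_probes,
        cn_state=cn,
    )


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_intervals(rng, n, chrom="1", span=100):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, span // 2 + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture
def patients():
    return [
        PatientRecord("P1", 38.0, 5.0, 1),
        PatientRecord("P2", 44.9, 10.0, 0),
        PatientRecord("P3", 45.0, 8.0, 1),
        PatientRecord("P4", 61.0, 12.0, 0),
        PatientRecord("P5", 29.5, 3.0, 1),
        PatientRecord("P6", 52.0, 15.0, 0),
    ]


@pytest.fixture
def small_sim_config():
    """Five young-specific planted regions plus one planted in both groups."""
    planted = [
        PlantedRegion("1", 50_000_000, 50_250_000, "gain", "young", 0.45, 300.0,
                      expression_beta=1.0, survival_log_hazard=0.7),
        PlantedRegion("2", 100_000_000, 100_300_000, "loss", "young", 0.40, 300.0,
                      expression_beta=0.8),
        PlantedRegion("5", 60_000_000, 60_200_000, "gain", "young", 0.35, 300.0),
        PlantedRegion("8", 20_000_000, 20_250_000, "loss", "young", 0.50, 300.0),
        PlantedRegion("11", 30_000_000, 30_300_000, "gain", "young", 0.40, 300.0),
        PlantedRegion("17", 40_000_000, 40_200_000, "gain", "both", 0.40, 300.0),
    ]
    return SimConfig(planted_regions=planted, n_young=100, n_old=150,
                     noise_rate=0.2, seed=1)
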