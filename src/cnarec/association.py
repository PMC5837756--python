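"""CNA-expression association (eQTL) and disease-specific survival analysis.

The eQTL model is a logistic regression of binarized-by-mean expression
on binary CNA carrier status; for a single binary predictor the fitted
odds ratio equals the 2x2 cross-product ratio, which the tests exploit as
an oracle.  Survival uses Kaplan-Meier curves with a log-rank test for
carrier status and a Cox proportional-hazards fit for continuous
expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EqtlResult",
    "SurvivalResult",
    "read_expression",
    "binarize_by_mean",
    "eqtl_test",
    "adjust_bh",
    "km_by_status",
    "cox_expression",
    "eqtl_table",
    "survival_table",
]


class NoContrastError(ValueError):
    """All observations fall in one group / one value: nothing to test."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a gene x sample expression matrix (TSV, genes as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def binarize_by_mean(values: np.ndarray | pd.Series) -> np.ndarray:
    """1 where the value exceeds the across-sample mean, else 0.

    A constant vector yields all zeros with a warning (degenerate
    response for any downstream regression).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("binarize_by_mean needs >= 2 samples")
    if np.isnan(arr).any():
        raise ValueError("missing values must be dropped before binarization")
    mean = arr.mean()
    out = (arr > mean).astype(int)
    if not out.any() and (arr == arr[0]).all():
        warnings.warn("constant expression vector: binarized response is all zero",
                      stacklevel=2)
    return out


@dataclass
class EqtlResult:
    gene: str
    alteration_type: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_mutated: int
    n_wildtype: int
    counts_2x2: tuple[int, int, int, int]  # (mut-high, mut-low, wt-high, wt-low)
    separation: bool = False
    p_adjusted: float | None = None


def eqtl_test(
    expression_binary: np.ndarray | Sequence[int],
    status: np.ndarray | Sequence[bool],
    gene: str = "",
    alteration_type: str = "",
) -> EqtlResult:
    """Logistic regression of binarized expression on CNA carrier status.

    Reports exp(coefficient) as the odds ratio with a Wald 95% CI and
    p-value, plus the underlying 2x2 table.  A zero cell switches to the
    Haldane-Anscombe-corrected table estimate and flags separation.
    """
    y = np.asarray(expression_binary, dtype=int)
    x = np.asarray(status, dtype=bool)
    if y.shape != x.shape:
        raise ValueError("expression and status vectors must align")
    if x.all() or not x.any():
        raise NoContrastError("no contrast: all samples mutated or all wildtype")

    a = int(((x) & (y == 1)).sum())   # mutated, high expression
    b = int(((x) & (y == 0)).sum())   # mutated, low
    c = int(((~x) & (y == 1)).sum())  # wildtype, high
    d = int(((~x) & (y == 0)).sum())  # wildtype, low
    counts = (a, b, c, d)

    if min(counts) == 0:
        # Haldane-Anscombe: +0.5 to every cell; Wald CI from log-OR variance.
        aa, bb, cc, dd = (v + 0.5 for v in counts)
        log_or = math.log(aa * dd / (bb * cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        z = log_or / se
        p = 2 * stats.norm.sf(abs(z))
        return EqtlResult(
            gene=gene,
            alteration_type=alteration_type,
            odds_ratio=math.exp(log_or),
            ci95=(math.exp(log_or - 1.959963984540054 * se),
                  math.exp(log_or + 1.959963984540054 * se)),
            p_value=float(p),
            n_mutated=a + b,
            n_wildtype=c + d,
            counts_2x2=counts,
            separation=True,
        )

    import statsmodels.api as sm

    design = sm.add_constant(x.astype(float))
    fit = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-10)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    lo, hi = fit.conf_int()[1]
    return EqtlResult(
        gene=gene,
        alteration_type=alteration_type,
        odds_ratio=math.exp(beta),
        ci95=(math.exp(float(lo)), math.exp(float(hi))),
        p_value=p,
        n_mutated=a + b,
        n_wildtype=c + d,
        counts_2x2=counts,
    )


def adjust_bh(results: Sequence[EqtlResult]) -> list[EqtlResult]:
    """Benjamini-Hochberg adjustment across all tested genes (in place)."""
    if not results:
        return list(results)
    _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for r, qv in zip(results, q):
        r.p_adjusted = float(qv)
    return list(results)


@dataclass
class SurvivalResult:
    gene: str
    analysis: str  # "km_logrank_status" or "cox_expression"
    alteration_type: str = ""
    hazard_ratio: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    logrank_p: float | None = None
    median_survival: dict[str, float] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)


def km_by_status(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    gene: str = "",
    alteration_type: str = "",
) -> SurvivalResult:
    """Kaplan-Meier curves for two groups, log-rank p and per-group medians.

    The median is the first time at which the product-limit estimate drops
    to <= 0.5 (infinity when the curve never crosses it).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"km_by_status needs exactly 2 groups, got {labels}")
    if events.sum() < 1:
        raise ValueError("no events observed")
    medians: dict[str, float] = {}
    counts: dict[str, int] = {}
    for label in labels:
        mask = groups == label
        if not mask.any():
            raise ValueError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        medians[label] = float(kmf.median_survival_time_)
        counts[label] = int(mask.sum())
    m0 = groups == labels[0]
    lr = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
    return SurvivalResult(
        gene=gene,
        analysis="km_logrank_status",
        alteration_type=alteration_type,
        logrank_p=float(lr.p_value),
        median_survival=medians,
        n_per_group=counts,
    )


def cox_expression(
    times: Sequence[float],
    events: Sequence[int],
    expression: Sequence[float],
    standardize: bool = True,
    gene: str = "",
    alteration_type: str = "",
) -> SurvivalResult:
    """Cox proportional-hazards fit of survival on one continuous covariate.

    The covariate is z-scored by default, so the hazard ratio is per
    standard deviation of expression.
    """
    x = np.asarray(expression, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.unique(x).size < 2:
        raise NoContrastError("no contrast: all covariate values equal")
    if e.sum() < 1:
        raise ValueError("no events observed")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    hr = float(np.exp(cph.params_["x"]))
    lo, hi = cph.confidence_intervals_.loc["x"]
    return SurvivalResult(
        gene=gene,
        analysis="cox_expression",
        alteration_type=alteration_type,
        hazard_ratio=hr,
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=float(cph.summary.loc["x", "p"]),
        n_per_group={"total": len(df), "events": int(e.sum())},
    )


def _fmt(x: float | None) -> str:
    return "NA" if x is None or (isinstance(x, float) and not math.isfinite(x)) else f"{x:.6g}"


def eqtl_table(results: Sequence[EqtlResult], path: str | Path) -> None:
    """TSV mirroring the published logistic-regression table layout."""
    rows = [
        {
            "Gene": r.gene,
            "CopyNumberState": r.alteration_type,
            "P": _fmt(r.p_value),
            "Padj": _fmt(r.p_adjusted),
            "OR": _fmt(r.odds_ratio),
            "CI95_low": _fmt(r.ci95[0]),
            "CI95_high": _fmt(r.ci95[1]),
            "nMutated": r.n_mutated,
            "nWildtype": r.n_wildtype,
            "Separation": int(r.separation),
        }
        for r in results
    ]
    cols = ["Gene", "CopyNumberState", "P", "Padj", "OR", "CI95_low", "CI95_high",
            "nMutated", "nWildtype", "Separation"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def survival_table(results: Sequence[SurvivalResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row = {
            "Gene": r.gene,
            "CNAtype": r.alteration_type,
            "Analysis": r.analysis,
            "P": _fmt(r.p_value),
            "HR": _fmt(r.hazard_ratio),
            "CI95_low": _fmt(r.ci95[0]) if r.ci95 else "NA",
            "CI95_high": _fmt(r.ci95[1]) if r.ci95 else "NA",
            "LogrankP": _fmt(r.logrank_p),
        }
        for label, med in r.median_survival.items():
            row[f"Median_{label}"] = _fmt(med)
        for label, n in r.n_per_group.items():
            row[f"N_{label}"] = n
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
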