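"""Time-to-onset (TTO) analysis with Weibull failure-type classification.

TTO is the number of whole days from the earliest full-precision therapy
start of a drug to the case's adverse-event onset date. Negative intervals
(onset before start — present in real spontaneous reports) and intervals
involving missing or partial dates are excluded from all statistics and
fits but are reported in their own segment.

Per-drug onset samples are fitted with a two-parameter Weibull
distribution by maximum likelihood; the shape parameter's 95% confidence
interval classifies the hazard over time: entirely below 1 -> early
failure (decreasing hazard), containing 1 -> random failure (constant
hazard), entirely above 1 -> wearout failure (increasing hazard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from faerspv.casestore import CaseReport
from faerspv.dates import days_between

VALID = "valid"
NEGATIVE = "negative"
MISSING = "missing"
PARTIAL = "partial-date"

#: Segment labels, inclusive integer day ranges; >360 is open-ended.
SEGMENTS: List[Tuple[str, int, Optional[int]]] = [
    ("0-30d", 0, 30),
    ("31-60d", 31, 60),
    ("61-90d", 61, 90),
    ("91-120d", 91, 120),
    ("121-150d", 121, 150),
    ("151-180d", 151, 180),
    ("181-360d", 181, 360),
    (">360d", 361, None),
]
MISSING_SEGMENT = "Missing or Abnormal Values (Less than 0)"


@dataclass
class OnsetRecord:
    caseid: str
    drug: Optional[str]
    status: str
    tto_days: Optional[int] = None

    def __post_init__(self):
        assert (self.tto_days is not None) == (self.status == VALID)


def compute_tto(case: CaseReport, drug: str) -> OnsetRecord:
    """Onset interval for one (case, drug) pair.

    Uses the case's event date and the drug's earliest full-precision
    therapy start. Day 0 (same-day onset) is valid.
    """
    start = None
    for use in case.drugs:
        if use.name == drug and use.start_dt is not None:
            if start is None or use.start_dt.sort_key() < start.sort_key():
                start = use.start_dt
    event = case.event_dt
    if start is None or event is None:
        return OnsetRecord(case.caseid, drug, MISSING)
    if not start.is_full or not event.is_full:
        return OnsetRecord(case.caseid, drug, PARTIAL)
    days = days_between(start, event)
    if days < 0:
        return OnsetRecord(case.caseid, drug, NEGATIVE)
    return OnsetRecord(case.caseid, drug, VALID, tto_days=days)


def case_level_tto(case: CaseReport) -> OnsetRecord:
    """One onset record per case: the smallest valid per-drug TTO, else the
    most informative non-valid status (negative > partial > missing)."""
    records = [compute_tto(case, name) for name in sorted(case.drug_names())]
    valid = [r for r in records if r.status == VALID]
    if valid:
        best = min(valid, key=lambda r: r.tto_days)
        return OnsetRecord(case.caseid, None, VALID, best.tto_days)
    for status in (NEGATIVE, PARTIAL, MISSING):
        if any(r.status == status for r in records):
            return OnsetRecord(case.caseid, None, status)
    return OnsetRecord(case.caseid, None, MISSING)


@dataclass
class TTOSegmentation:
    counts: Dict[str, int]
    total: int

    def percentages(self) -> Dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}


def segment_tto(records: Sequence[OnsetRecord]) -> TTOSegmentation:
    """Assign every record to exactly one segment (missing/negative pooled)."""
    counts = {label: 0 for label, _, _ in SEGMENTS}
    counts[MISSING_SEGMENT] = 0
    for rec in records:
        if rec.status != VALID:
            counts[MISSING_SEGMENT] += 1
            continue
        d = rec.tto_days
        for label, lo, hi in SEGMENTS:
            if d >= lo and (hi is None or d <= hi):
                counts[label] += 1
                break
    seg = TTOSegmentation(counts=counts, total=len(records))
    assert sum(counts.values()) == len(records)
    return seg


@dataclass
class TTOSummary:
    n: int
    n_missing: int
    mean: float = float("nan")
    sd: float = float("nan")
    median: float = float("nan")
    q1: float = float("nan")
    q3: float = float("nan")
    min: float = float("nan")
    max: float = float("nan")


def summarize_tto(records: Sequence[OnsetRecord]) -> TTOSummary:
    """Descriptive statistics over valid onset days only.

    Quartiles use linear interpolation between order statistics; sd is the
    sample standard deviation (n - 1 denominator).
    """
    values = np.array([r.tto_days for r in records if r.status == VALID], dtype=float)
    n_missing = len(records) - len(values)
    if len(values) == 0:
        return TTOSummary(n=0, n_missing=n_missing)
    return TTOSummary(
        n=len(values), n_missing=n_missing,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        median=float(np.median(values)),
        q1=float(np.percentile(values, 25)),
        q3=float(np.percentile(values, 75)),
        min=float(values.min()),
        max=float(values.max()),
    )


EARLY = "early"
RANDOM = "random"
WEAROUT = "wearout"
DEGENERATE = "degenerate"


@dataclass
class WeibullFit:
    n: int
    scale: float = float("nan")
    scale_low: float = float("nan")
    scale_high: float = float("nan")
    shape: float = float("nan")
    shape_low: float = float("nan")
    shape_high: float = float("nan")
    failure_type: str = DEGENERATE
    converged: bool = False
    loglik: float = float("nan")


def _weibull_negloglik(log_params: np.ndarray, x: np.ndarray) -> float:
    log_scale, log_shape = log_params
    scale, shape = math.exp(log_scale), math.exp(log_shape)
    z = x / scale
    return -float(np.sum(np.log(shape / scale) + (shape - 1) * np.log(z) - z ** shape))


def _observed_information(log_params: np.ndarray, x: np.ndarray,
                          eps: float = 1e-5) -> np.ndarray:
    """Hessian of the negative log-likelihood in (log scale, log shape)."""
    h = np.zeros((2, 2))
    f0 = _weibull_negloglik(log_params, x)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = eps
            ej = np.zeros(2); ej[j] = eps
            fpp = _weibull_negloglik(log_params + ei + ej, x)
            fpm = _weibull_negloglik(log_params + ei - ej, x)
            fmp = _weibull_negloglik(log_params - ei + ej, x)
            fmm = _weibull_negloglik(log_params - ei - ej, x)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


def fit_weibull(sample: Iterable[float], zero_substitute: float = 0.5) -> WeibullFit:
    """Two-parameter Weibull maximum-likelihood fit with Wald CIs.

    Zero-day onsets are replaced by ``zero_substitute`` (default half a
    day) for fitting only — the Weibull support is strictly positive.
    95% CIs are Wald intervals on (log scale, log shape) from the observed
    information matrix, back-transformed. Samples with (near-)zero
    variance or a non-convergent likelihood are flagged degenerate.
    """
    x = np.asarray(list(sample), dtype=float)
    if len(x) < 3:
        raise ValueError(f"insufficient data for Weibull fit (n={len(x)} < 3)")
    if np.any(x < 0):
        raise ValueError("negative onset values must be excluded before fitting")
    x = np.where(x == 0, zero_substitute, x)
    fit = WeibullFit(n=len(x))
    if np.ptp(x) == 0 or np.std(x) / np.mean(x) < 1e-9:
        return fit  # all identical -> shape unidentifiable
    try:
        shape0, _, scale0 = stats.weibull_min.fit(x, floc=0)
        theta0 = np.array([math.log(scale0), math.log(shape0)])
        res = optimize.minimize(_weibull_negloglik, theta0, args=(x,),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 2000})
        theta = res.x if res.fun <= _weibull_negloglik(theta0, x) else theta0
        scale, shape = math.exp(theta[0]), math.exp(theta[1])
        info = _observed_information(theta, x)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)) or np.any(np.diag(cov) <= 0):
            return fit
    except (ValueError, np.linalg.LinAlgError, OverflowError):
        return fit
    fit.scale = scale
    fit.shape = shape
    fit.scale_low = math.exp(theta[0] - 1.96 * se[0])
    fit.scale_high = math.exp(theta[0] + 1.96 * se[0])
    fit.shape_low = math.exp(theta[1] - 1.96 * se[1])
    fit.shape_high = math.exp(theta[1] + 1.96 * se[1])
    fit.converged = True
    fit.loglik = -_weibull_negloglik(theta, x)
    fit.failure_type = classify_failure(fit)
    return fit


def classify_failure(fit: WeibullFit) -> str:
    """Failure type from the shape parameter's confidence interval."""
    if not fit.converged or math.isnan(fit.shape_low) or math.isnan(fit.shape_high):
        return DEGENERATE
    return classify_shape_ci(fit.shape_low, fit.shape_high)


def classify_shape_ci(shape_low: float, shape_high: float) -> str:
    """early if the CI lies below 1, wearout if above, random if it spans 1."""
    if shape_high < 1.0:
        return EARLY
    if shape_low > 1.0:
        return WEAROUT
    return RANDOM


def drug_tto_analysis(target_cases: Dict[str, CaseReport], min_n: int = 3):
    """Per-drug onset samples, summaries and Weibull fits for target cases.

    Returns a list of dict rows (drug, n, median, q1, q3, scale and shape
    with CIs, failure type) over drugs with at least ``min_n`` valid
    onsets, ranked by n descending then drug name.
    """
    import pandas as pd

    by_drug: Dict[str, List[int]] = {}
    for case in target_cases.values():
        for name in case.drug_names():
            rec = compute_tto(case, name)
            if rec.status == VALID:
                by_drug.setdefault(name, []).append(rec.tto_days)
    rows = []
    for drug in sorted(by_drug):
        values = by_drug[drug]
        if len(values) < min_n:
            continue
        summary = summarize_tto([OnsetRecord(str(i), drug, VALID, v)
                                 for i, v in enumerate(values)])
        fit = fit_weibull(values)
        rows.append({
            "drug": drug, "n": len(values),
            "median": summary.median, "q1": summary.q1, "q3": summary.q3,
            "scale": fit.scale, "scale_low": fit.scale_low,
            "scale_high": fit.scale_high,
            "shape": fit.shape, "shape_low": fit.shape_low,
            "shape_high": fit.shape_high,
            "failure_type": fit.failure_type,
        })
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["n", "drug"], ascending=[False, True],
                                  kind="mergesort").reset_index(drop=True)
    return frame
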