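"""Disproportionality statistics over drug x event 2x2 tables.

The unit of counting is the deduplicated case (one patient report). For a
target event and each drug the corpus is cross-classified as

    a = cases listing the drug with the target event
    b = cases listing the drug without it
    c = cases with the event but not the drug
    d = the rest,            N = a + b + c + d.

Four estimators are computed as they are conventionally defined in
spontaneous-report signal detection:

* ROR = ad/(bc), Wald 95% CI on the log scale with
  SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d).
* PRR = (a/(a+b)) / (c/(c+d)), SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)),
  accompanied by the plain Pearson chi-square (no continuity correction).
* BCPNN information component IC = log2((a + 0.5)/(E + 0.5)) with
  E = (a+b)(a+c)/N, and closed-form credible bounds
  IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2),
  IC975 = IC + 2.4 (a+0.5)^(-1/2) - 0.5 (a+0.5)^(-3/2);
  the full Bayesian E(IC), V(IC) and IC - 2SD are computed from the
  Dirichlet prior with counts alpha1 = beta1 = gamma11 = 1, alpha = beta = 2.
* EBGM here is the crude relative reporting ratio a N / ((a+c)(a+b)) with a
  log-normal Wald interval (EBGM05 = lower 95% bound) — not the
  gamma-Poisson shrinkage estimator of the same name.

A drug-event pair is a signal when all four criteria hold: a >= 3 with the
ROR CI lower bound > 1; a >= 3 with PRR >= 2 and chi-square >= 4;
IC025 > 0; EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from faerspv.casestore import CaseReport

Z95 = 1.96
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one drug x one target event, with FAERS-style margins."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n_observed(self) -> int:
        return self.a

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_effect(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_expected(self) -> float:
        return self.n_drug * self.n_effect / self.n_total

    def corrected(self) -> "CorrectedTable":
        return CorrectedTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class CorrectedTable:
    """Haldane-Anscombe +0.5 cells (floats), used when a cell is zero."""

    a: float
    b: float
    c: float
    d: float


@dataclass(frozen=True)
class BcpnnHyperparams:
    """Dirichlet prior counts of the BCPNN information component."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, table: ContingencyTable) -> float:
        n = table.n_total
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((table.n_drug + self.alpha1) * (table.n_effect + self.beta1)))


DEFAULT_HYPERPARAMS = BcpnnHyperparams()


@dataclass
class Estimate:
    value: float
    low: Optional[float] = None
    high: Optional[float] = None
    corrected: bool = False  # Haldane-Anscombe correction applied


def _wald_log_ci(estimate: float, se: float) -> Tuple[float, float]:
    return (math.exp(math.log(estimate) - Z95 * se),
            math.exp(math.log(estimate) + Z95 * se))


def _cells(table: ContingencyTable):
    """Raw cells, or +0.5-corrected cells when any cell is zero."""
    if table.has_zero_cell():
        t = table.corrected()
        return t.a, t.b, t.c, t.d, True
    return float(table.a), float(table.b), float(table.c), float(table.d), False


def ror(table: ContingencyTable) -> Estimate:
    """Reporting odds ratio ad/(bc) with Wald 95% CI on the log scale."""
    a, b, c, d, corrected = _cells(table)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low, high = _wald_log_ci(est, se)
    return Estimate(est, low, high, corrected)


def prr(table: ContingencyTable) -> Estimate:
    """Proportional reporting ratio with Wald 95% CI on the log scale."""
    a, b, c, d, corrected = _cells(table)
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    low, high = _wald_log_ci(est, se)
    return Estimate(est, low, high, corrected)


def chi_square(table: ContingencyTable) -> float:
    """Pearson chi-square, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(a+c)(c+d)(b+d)); NaN on a zero margin.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    denom = (a + b) * (a + c) * (c + d) * (b + d)
    if denom == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def ic_simple(table: ContingencyTable, smoothed: bool = True):
    """Information component with closed-form 95% credible bounds.

    IC = log2((a + 0.5)/(E + 0.5)) where E = Ndrug * Neffect / Ntotal;
    smoothed=False gives the unsmoothed log2(a/E) point estimate (the
    credible bounds always use the smoothed form). Returns (ic, ic025, ic975).
    """
    a = table.a
    e = table.n_expected
    ic_s = math.log2((a + 0.5) / (e + 0.5))
    if smoothed or a == 0 or e == 0:
        ic = ic_s
    else:
        ic = math.log2(a / e)
    s = a + 0.5
    ic025 = ic_s - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    ic975 = ic_s + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    return ic, ic025, ic975


def bcpnn_full(table: ContingencyTable,
               hyper: BcpnnHyperparams = DEFAULT_HYPERPARAMS):
    """Posterior mean, variance and lower 2-SD bound of the IC.

    E(IC) = log2[(a + g11)(N + alpha)(N + beta) /
                 ((N + gamma)(a+b + alpha1)(a+c + beta1))],
    V(IC) = (1/ln2)^2 * [ (N - a + gamma - g11)/((a + g11)(1 + N + gamma))
                        + (N - (a+b) + alpha - alpha1)/((a+b + alpha1)(1 + N + alpha))
                        + (N - (a+c) + beta - beta1)/((a+c + beta1)(1 + N + beta)) ],
    IC-2SD = E(IC) - 2 sqrt(V(IC)). Returns (e_ic, v_ic, ic_minus_2sd).
    """
    a = float(table.a)
    n = float(table.n_total)
    nd = float(table.n_drug)
    ne = float(table.n_effect)
    g = hyper.gamma(table)
    e_ic = math.log2(
        (a + hyper.gamma11) * (n + hyper.alpha) * (n + hyper.beta)
        / ((n + g) * (nd + hyper.alpha1) * (ne + hyper.beta1)))
    v_ic = (1.0 / LN2 ** 2) * (
        (n - a + g - hyper.gamma11) / ((a + hyper.gamma11) * (1 + n + g))
        + (n - nd + hyper.alpha - hyper.alpha1) / ((nd + hyper.alpha1) * (1 + n + hyper.alpha))
        + (n - ne + hyper.beta - hyper.beta1) / ((ne + hyper.beta1) * (1 + n + hyper.beta)))
    return e_ic, v_ic, e_ic - 2.0 * math.sqrt(v_ic)


def ebgm(table: ContingencyTable) -> Estimate:
    """Crude relative reporting ratio a*N/((a+c)(a+b)) with log-normal CI.

    The lower bound (Estimate.low) is the EBGM05 signal quantity.
    """
    a, b, c, d, corrected = _cells(table)
    n = a + b + c + d
    est = a * n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low, high = _wald_log_ci(est, se)
    return Estimate(est, low, high, corrected)


@dataclass
class SignalStats:
    """All estimators, intervals and criterion flags for one 2x2 table."""

    table: ContingencyTable
    ror: Estimate = field(default=None)
    prr: Estimate = field(default=None)
    chi2: float = float("nan")
    ic: float = float("nan")
    ic025: float = float("nan")
    ic975: float = float("nan")
    e_ic: float = float("nan")
    v_ic: float = float("nan")
    ic_minus_2sd: float = float("nan")
    ebgm: Estimate = field(default=None)
    ror_signal: bool = False
    prr_signal: bool = False
    bcpnn_signal: bool = False
    mgps_signal: bool = False
    signal_all: bool = False


def evaluate_signal(stats: SignalStats, a: int,
                    bcpnn_criterion: str = "ic025") -> SignalStats:
    """Apply the conjunctive signal criteria in place and return stats.

    bcpnn_criterion: "ic025" (default, IC025 > 0) or "ic_minus_2sd"
    (E(IC) - 2 SD > 0).
    """
    stats.ror_signal = bool(a >= 3 and stats.ror.low is not None and stats.ror.low > 1.0)
    stats.prr_signal = bool(a >= 3 and stats.prr.value >= 2.0
                            and not math.isnan(stats.chi2) and stats.chi2 >= 4.0)
    if bcpnn_criterion == "ic_minus_2sd":
        stats.bcpnn_signal = bool(stats.ic_minus_2sd > 0.0)
    else:
        stats.bcpnn_signal = bool(stats.ic025 > 0.0)
    stats.mgps_signal = bool(stats.ebgm.low is not None and stats.ebgm.low > 2.0)
    stats.signal_all = (stats.ror_signal and stats.prr_signal
                        and stats.bcpnn_signal and stats.mgps_signal)
    return stats


def compute_signal_stats(table: ContingencyTable,
                         hyper: BcpnnHyperparams = DEFAULT_HYPERPARAMS,
                         ic_smoothed: bool = True,
                         bcpnn_criterion: str = "ic025") -> SignalStats:
    """Compute every estimator and the criterion flags for one table."""
    stats = SignalStats(table=table)
    stats.ror = ror(table)
    stats.prr = prr(table)
    stats.chi2 = chi_square(table)
    stats.ic, stats.ic025, stats.ic975 = ic_simple(table, smoothed=ic_smoothed)
    stats.e_ic, stats.v_ic, stats.ic_minus_2sd = bcpnn_full(table, hyper)
    stats.ebgm = ebgm(table)
    return evaluate_signal(stats, table.a, bcpnn_criterion)


# ---------------------------------------------------------------------------
# Table building and stratified runs
# ---------------------------------------------------------------------------

STRATUM_AXES = ("sex", "age_band", "reporter", "none")


def _stratum_value(case: CaseReport, axis: str) -> str:
    if axis == "sex":
        return case.sex if case.sex in ("F", "M") else "Not Specified"
    if axis == "age_band":
        return case.age_band
    if axis == "reporter":
        return case.reporter
    raise ValueError(f"unknown stratum axis: {axis!r}")


def build_tables(corpus: Dict[str, CaseReport],
                 target_pt_codes: Iterable[str],
                 stratum: Optional[Tuple[str, str]] = None
                 ) -> Dict[str, ContingencyTable]:
    """One 2x2 table per drug over the (optionally stratified) corpus.

    Each case contributes once per distinct drug regardless of how many
    drug entries list it; a + b + c + d equals the number of cases in the
    stratum for every drug.
    """
    if not corpus:
        raise ValueError("empty corpus")
    targets = {str(t) for t in target_pt_codes}
    if stratum is not None and stratum[0] != "none":
        axis, level = stratum
        cases = [c for c in corpus.values() if _stratum_value(c, axis) == level]
    else:
        cases = list(corpus.values())
    n = len(cases)
    n_effect = 0
    drug_n: Dict[str, int] = {}
    drug_a: Dict[str, int] = {}
    for case in cases:
        is_target = bool(case.pt_codes() & targets)
        if is_target:
            n_effect += 1
        for name in case.drug_names():
            drug_n[name] = drug_n.get(name, 0) + 1
            if is_target:
                drug_a[name] = drug_a.get(name, 0) + 1
    tables = {}
    for name, nd in drug_n.items():
        a = drug_a.get(name, 0)
        tables[name] = ContingencyTable(a=a, b=nd - a, c=n_effect - a,
                                        d=n - nd - (n_effect - a))
    return tables


def signal_frame(tables: Dict[str, ContingencyTable],
                 hyper: BcpnnHyperparams = DEFAULT_HYPERPARAMS,
                 ic_smoothed: bool = True,
                 bcpnn_criterion: str = "ic025",
                 min_a: int = 1) -> pd.DataFrame:
    """Ranked signal table (a descending, drug name ascending on ties)."""
    rows = []
    for drug, table in tables.items():
        if table.a < min_a:
            continue
        s = compute_signal_stats(table, hyper, ic_smoothed, bcpnn_criterion)
        rows.append({
            "drug": drug, "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "ROR": s.ror.value, "ROR_low": s.ror.low, "ROR_high": s.ror.high,
            "PRR": s.prr.value, "PRR_low": s.prr.low, "PRR_high": s.prr.high,
            "chi2": s.chi2,
            "IC": s.ic, "IC025": s.ic025, "IC975": s.ic975,
            "EIC": s.e_ic, "IC_2SD": s.ic_minus_2sd,
            "EBGM": s.ebgm.value, "EBGM05": s.ebgm.low,
            "ror_signal": s.ror_signal, "prr_signal": s.prr_signal,
            "bcpnn_signal": s.bcpnn_signal, "mgps_signal": s.mgps_signal,
            "signal_all": s.signal_all,
            "corrected": s.ror.corrected,
        })
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["a", "drug"], ascending=[False, True],
                                  kind="mergesort").reset_index(drop=True)
    return frame


def run_stratified(corpus: Dict[str, CaseReport],
                   target_pt_codes: Iterable[str],
                   axes: Iterable[str],
                   **kwargs) -> Dict[Tuple[str, str], pd.DataFrame]:
    """Rebuild tables and statistics within each level of each axis.

    Ntotal inside a stratum is the stratum's case count; drugs with no
    exposure in a stratum are absent from its table.
    """
    out: Dict[Tuple[str, str], pd.DataFrame] = {}
    for axis in axes:
        levels = sorted({_stratum_value(c, axis) for c in corpus.values()})
        for level in levels:
            tables = build_tables(corpus, target_pt_codes, stratum=(axis, level))
            frame = signal_frame(tables, **kwargs)
            if frame.empty or int(frame["a"].sum()) == 0:
                import logging
                logging.getLogger(__name__).info(
                    "stratum %s=%s has no target cases", axis, level)
            out[(axis, level)] = frame
    return out
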