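"""End-to-end orchestration: clean -> standardize -> select -> statistics.

``run`` executes the stages in the order of a standard spontaneous-report
analysis — deduplication, deletion-list purge, dictionary standardization,
target-case selection, disproportionality statistics (overall and within
strata), descriptive profiling, and time-to-onset analysis — and writes a
deterministic report bundle (TSVs rounded to 2 decimals, a full-precision
JSON signal table, flow-count JSON, and a stage log).
"""

from __future__ import annotations

import dataclasses
import json
import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from faerspv.casestore import (
    AGE_BANDS,
    CaseReport,
    FlowCounts,
    NOT_SPECIFIED,
    TermMap,
    build_corpus,
)
from faerspv.disproportionality import run_stratified, build_tables, signal_frame
from faerspv.io import OUTCOME_CODES, QuarterBundle, read_bundle
from faerspv.synthetic import SyntheticConfig, default_term_map, generate
from faerspv.tto import (
    MISSING_SEGMENT,
    SEGMENTS,
    case_level_tto,
    drug_tto_analysis,
    segment_tto,
    summarize_tto,
)

logger = logging.getLogger(__name__)

OUTCOME_LABELS = {
    "LT": "Life-Threatening",
    "HO": "Hospitalization - Initial or Prolonged",
    "DS": "Disability",
    "DE": "Death",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent Impairment/Damage",
    "OT": "Other (Other serious significant medical events)",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``quarter_dirs`` (with ``quarter_labels``) or
    ``synthetic`` must be provided.
    """

    quarter_dirs: Optional[List[str]] = None
    quarter_labels: Optional[List[str]] = None
    synthetic: Optional[SyntheticConfig] = None
    term_map: Optional[TermMap] = None
    target_pt_codes: Tuple[str, ...] = ("10001052",)
    roles: Optional[Set[str]] = None  # e.g. {"PS", "SS"}; None = all roles
    strata_axes: Tuple[str, ...] = ()
    bcpnn_criterion: str = "ic025"
    ic_smoothed: bool = True
    min_a: int = 1
    out_dir: str = "results"
    strict: bool = False

    def validate(self) -> None:
        has_paths = bool(self.quarter_dirs)
        has_synth = self.synthetic is not None
        if has_paths == has_synth:
            raise ValueError(
                "exactly one of quarter_dirs / synthetic must be given")


@dataclass
class DescriptiveProfile:
    """The descriptive case-profile block of a pharmacovigilance report."""

    n_cases: int
    sex: Dict[str, int]
    age_bands: Dict[str, int]
    age_summary: Dict[str, float]
    years: Dict[int, int]
    reporter: Dict[str, int]
    outcomes: Dict[str, int]  # non-exclusive; may sum past n_cases
    countries: Dict[str, int]
    tto_segments: Dict[str, int]
    tto_summary: Dict[str, float]

    def as_rows(self) -> List[Tuple[str, str, float, float]]:
        """(section, label, count, percent) rows in report order."""
        rows = []

        def pct(v):
            return 100.0 * v / self.n_cases if self.n_cases else 0.0

        for label in ("F", "M", NOT_SPECIFIED):
            v = self.sex.get(label, 0)
            name = {"F": "Female", "M": "Male"}.get(label, label)
            rows.append(("Gender", name, v, pct(v)))
        for band in AGE_BANDS:
            v = self.age_bands.get(band, 0)
            rows.append(("Age", band, v, pct(v)))
        for year in sorted(self.years):
            rows.append(("Reporting Year", str(year), self.years[year],
                         pct(self.years[year])))
        for label in sorted(self.reporter):
            rows.append(("Reporter", label, self.reporter[label],
                         pct(self.reporter[label])))
        for code in OUTCOME_CODES:
            v = self.outcomes.get(code, 0)
            rows.append(("Outcome", OUTCOME_LABELS[code], v, pct(v)))
        for label, _, _ in SEGMENTS:
            v = self.tto_segments.get(label, 0)
            rows.append(("Time to Onset", label, v, pct(v)))
        v = self.tto_segments.get(MISSING_SEGMENT, 0)
        rows.append(("Time to Onset", MISSING_SEGMENT, v, pct(v)))
        return rows


def profile(target_cases: Dict[str, CaseReport], top_countries: int = 10
            ) -> DescriptiveProfile:
    """Descriptive profile of the target-case subset.

    Sex / age band / year / reporter are exclusive axes whose percentages
    sum to 100; outcome codes are non-exclusive by design.
    """
    if not target_cases:
        logger.warning("profile requested for zero target cases")
    sex: Dict[str, int] = {}
    bands: Dict[str, int] = {}
    years: Dict[int, int] = {}
    reporter: Dict[str, int] = {}
    outcomes: Dict[str, int] = {}
    countries: Dict[str, int] = {}
    ages: List[float] = []
    for case in target_cases.values():
        s = case.sex if case.sex in ("F", "M") else NOT_SPECIFIED
        sex[s] = sex.get(s, 0) + 1
        bands[case.age_band] = bands.get(case.age_band, 0) + 1
        if case.age_years is not None:
            ages.append(case.age_years)
        if case.report_year is not None:
            years[case.report_year] = years.get(case.report_year, 0) + 1
        reporter[case.reporter] = reporter.get(case.reporter, 0) + 1
        for code in case.outcomes:
            outcomes[code] = outcomes.get(code, 0) + 1
        country = case.country or NOT_SPECIFIED
        countries[country] = countries.get(country, 0) + 1

    import numpy as np
    if ages:
        arr = np.asarray(ages)
        age_summary = {
            "n": float(len(arr)), "missing": float(len(target_cases) - len(arr)),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "min": float(arr.min()), "max": float(arr.max()),
        }
    else:
        age_summary = {"n": 0.0, "missing": float(len(target_cases))}

    onset_records = [case_level_tto(c) for c in target_cases.values()]
    seg = segment_tto(onset_records)
    summ = summarize_tto(onset_records)
    top = dict(sorted(countries.items(), key=lambda kv: (-kv[1], kv[0]))
               [:top_countries])
    return DescriptiveProfile(
        n_cases=len(target_cases), sex=sex, age_bands=bands,
        age_summary=age_summary, years=years, reporter=reporter,
        outcomes=outcomes, countries=top, tto_segments=seg.counts,
        tto_summary={
            "n": float(summ.n), "missing": float(summ.n_missing),
            "mean": summ.mean, "sd": summ.sd, "median": summ.median,
            "q1": summ.q1, "q3": summ.q3, "min": summ.min, "max": summ.max,
        })


def _load_bundles(config: RunConfig) -> List[QuarterBundle]:
    if config.synthetic is not None:
        bundle, _ = generate(config.synthetic)
        return [bundle]
    labels = config.quarter_labels or [""] * len(config.quarter_dirs)
    return [read_bundle(d, lbl, strict=config.strict)
            for d, lbl in zip(config.quarter_dirs, labels)]


def _round_frame(frame: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(decimals)
    return out


def run(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results: corpus, target cases, flow
    counts, profile, signal frame(s) and TTO tables. Reruns with the same
    config and inputs produce identical outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []

    def stage(msg: str) -> None:
        # the written log is sequence-numbered, not wall-clock stamped, so
        # a rerun on identical inputs is byte-identical; timestamps appear
        # only on the live logging stream
        log_lines.append(f"[{len(log_lines) + 1:02d}] {msg}")
        logger.info(msg)

    stage("load: reading input bundles")
    bundles = _load_bundles(config)
    term_map = config.term_map
    if term_map is None:
        term_map = (default_term_map(config.synthetic)
                    if config.synthetic is not None else TermMap())
    n_raw = sum(len(b.demo) for b in bundles)
    stage(f"load: {len(bundles)} bundle(s), {n_raw} raw DEMO records")

    stage("clean: deduplicate + deletion lists + standardize + select")
    cases, target, flow, unmapped = build_corpus(
        bundles, term_map, config.target_pt_codes, roles=config.roles)
    stage(f"clean: raw={flow.raw_reports} duplicates={flow.duplicates_removed} "
          f"deleted={flow.deleted_by_list} unique={flow.unique_cases} "
          f"target={flow.target_cases}")

    stage("profile: descriptive summary of target cases")
    prof = profile(target)

    stage("signals: contingency tables + disproportionality statistics")
    tables = build_tables(cases, config.target_pt_codes)
    signals = signal_frame(tables, ic_smoothed=config.ic_smoothed,
                           bcpnn_criterion=config.bcpnn_criterion,
                           min_a=config.min_a)
    stage(f"signals: {len(signals)} drugs with a >= {config.min_a}, "
          f"{int(signals['signal_all'].sum()) if not signals.empty else 0} "
          f"meeting all four criteria")

    strata: Dict[Tuple[str, str], pd.DataFrame] = {}
    if config.strata_axes:
        stage(f"strata: recomputing within {', '.join(config.strata_axes)}")
        strata = run_stratified(cases, config.target_pt_codes,
                                config.strata_axes,
                                ic_smoothed=config.ic_smoothed,
                                bcpnn_criterion=config.bcpnn_criterion,
                                min_a=config.min_a)

    stage("tto: per-drug onset samples and Weibull fits")
    tto_frame = drug_tto_analysis(target)

    # ---- write the report bundle --------------------------------------
    flow_json = dataclasses.asdict(flow)
    (out_dir / "flow_counts.json").write_text(json.dumps(flow_json, indent=1))

    prof_rows = pd.DataFrame(prof.as_rows(),
                             columns=["section", "label", "count", "percent"])
    _round_frame(prof_rows).to_csv(out_dir / "profile.tsv", sep="\t", index=False)
    quant = pd.DataFrame([
        {"block": "age", **prof.age_summary},
        {"block": "tto", **prof.tto_summary},
    ])
    _round_frame(quant).to_csv(out_dir / "profile_quantitative.tsv",
                               sep="\t", index=False)

    _round_frame(signals).to_csv(out_dir / "signals.tsv", sep="\t", index=False)
    signals.to_json(out_dir / "signals.json", orient="records", indent=1)
    for (axis, level), frame in strata.items():
        safe = str(level).replace(" ", "_").replace("/", "-")
        _round_frame(frame).to_csv(out_dir / f"signals_{axis}_{safe}.tsv",
                                   sep="\t", index=False)
    _round_frame(tto_frame).to_csv(out_dir / "tto_weibull.tsv",
                                   sep="\t", index=False)
    if unmapped:
        pd.DataFrame(sorted(unmapped.items()),
                     columns=["verbatim", "count"]).to_csv(
            out_dir / "unmapped_drugs.tsv", sep="\t", index=False)
    stage("done")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {"cases": cases, "target": target, "flow": flow, "profile": prof,
            "signals": signals, "strata": strata, "tto": tto_frame,
            "unmapped": unmapped}
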