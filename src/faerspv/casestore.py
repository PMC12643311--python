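"""From raw quarter bundles to a deduplicated, standardized case corpus.

Deduplication follows the FDA-recommended rule for spontaneous reports:
among all versions sharing a CASEID, keep the one with the most recent
FDA_DT; on ties, keep the numerically highest PRIMARYID. Deletion-report
lists (published quarterly since 2019Q1) are applied afterwards by CASEID.
Event terms are annotated through a user-supplied preferred-term map
(PT code -> PT name, system organ class) and drug verbatims through a
verbatim -> ingredient map, standing in for the licensed MedDRA and WHO
drug dictionaries.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from faerspv.dates import PartialDate, date_sort_key
from faerspv.io import QuarterBundle, RawDemoRecord

logger = logging.getLogger(__name__)

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "Not Specified")

OCCUPATION_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "CN": "Consumer",
    "LW": "Lawyer",
}
NOT_SPECIFIED = "Not Specified"

#: Days per unit of each FAERS age code, expressed as years multiplier.
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 120.0


def normalize_age(age_value: Optional[float], age_unit: Optional[str]):
    """Convert a (value, unit) age to years; implausible values go missing.

    Returns (age_years or None, flag or None). Flags: "assumed-yr" when the
    unit is missing, "implausible" for results above 120 years, "negative"
    for negative inputs.
    """
    if age_value is None:
        return None, None
    if age_value < 0:
        return None, "negative"
    flag = None
    unit = age_unit
    if unit is None:
        unit = "YR"
        flag = "assumed-yr"
    factor = _AGE_FACTORS.get(unit.upper())
    if factor is None:
        return None, "bad-unit"
    years = age_value * factor
    if years > MAX_PLAUSIBLE_AGE:
        return None, "implausible"
    return years, flag


def age_band(age_years: Optional[float]) -> str:
    if age_years is None:
        return NOT_SPECIFIED
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


def reporter_category(occupation_code: Optional[str]) -> str:
    if occupation_code is None:
        return NOT_SPECIFIED
    return OCCUPATION_LABELS.get(occupation_code.upper(), NOT_SPECIFIED)


@dataclass
class TermMap:
    """Pluggable stand-in for the MedDRA PT/SOC and drug dictionaries."""

    pt_map: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    drug_map: Dict[str, str] = field(default_factory=dict)

    @staticmethod
    def normalize_verbatim(name: str) -> str:
        """Uppercase, strip punctuation, collapse whitespace."""
        cleaned = "".join(ch if ch.isalnum() or ch.isspace() else " "
                          for ch in name.upper())
        return " ".join(cleaned.split())

    def map_drug(self, verbatim: str) -> Tuple[str, bool]:
        """Return (standardized name, mapped?)."""
        key = self.normalize_verbatim(verbatim)
        if key in self.drug_map:
            return self.drug_map[key], True
        return f"unmapped:{verbatim}", False

    def map_pt(self, pt_code: Optional[str]):
        """Return (pt_name, soc_name) or (None, None)."""
        if pt_code is not None and pt_code in self.pt_map:
            return self.pt_map[pt_code]
        return None, None

    @classmethod
    def from_tsv(cls, pt_path: Optional[Union[str, Path]] = None,
                 drug_path: Optional[Union[str, Path]] = None) -> "TermMap":
        """Load from TSVs: (pt_code, pt_name, soc_name) and
        (verbatim_name, standardized_name), each with a header line."""
        tm = cls()
        if pt_path is not None:
            with open(pt_path, newline="", encoding="utf-8") as fh:
                reader = csv.reader(fh, delimiter="\t")
                next(reader, None)
                for row in reader:
                    if len(row) >= 3:
                        tm.pt_map[row[0].strip()] = (row[1].strip(), row[2].strip())
        if drug_path is not None:
            with open(drug_path, newline="", encoding="utf-8") as fh:
                reader = csv.reader(fh, delimiter="\t")
                next(reader, None)
                for row in reader:
                    if len(row) >= 2:
                        tm.drug_map[cls.normalize_verbatim(row[0])] = row[1].strip()
        return tm


@dataclass
class DrugUse:
    """One drug within a case: standardized name, unioned roles, earliest
    full-precision therapy start date."""

    name: str
    roles: Set[str] = field(default_factory=set)
    start_dt: Optional[PartialDate] = None
    mapped: bool = True


@dataclass
class Reaction:
    pt_code: Optional[str]
    pt_name: Optional[str]
    soc_name: Optional[str] = None


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    caseid: str
    primaryid: str
    fda_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate] = None
    sex: Optional[str] = None
    age_years: Optional[float] = None
    country: Optional[str] = None
    reporter: str = NOT_SPECIFIED
    drugs: List[DrugUse] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    outcomes: Set[str] = field(default_factory=set)

    @property
    def age_band(self) -> str:
        return age_band(self.age_years)

    @property
    def report_year(self) -> Optional[int]:
        return self.fda_dt.year if self.fda_dt is not None else None

    def drug_names(self) -> Set[str]:
        return {d.name for d in self.drugs}

    def pt_codes(self) -> Set[str]:
        return {r.pt_code for r in self.reactions if r.pt_code is not None}


@dataclass
class FlowCounts:
    """Report-flow accounting; raw - duplicates - deleted = unique."""

    raw_reports: int = 0
    duplicates_removed: int = 0
    deleted_by_list: int = 0
    unique_cases: int = 0
    target_cases: int = 0

    def check(self) -> None:
        assert self.raw_reports - self.duplicates_removed - self.deleted_by_list \
            == self.unique_cases
        assert self.target_cases <= self.unique_cases


def _pid_key(primaryid: str) -> Tuple[int, str]:
    """Numeric ordering of primaryids, with a string fallback for safety."""
    try:
        return (int(primaryid), primaryid)
    except ValueError:
        return (-1, primaryid)


def deduplicate(demo_records: Iterable[RawDemoRecord]):
    """Keep one DEMO version per caseid: latest FDA_DT, ties to highest
    numeric PRIMARYID. Unparseable FDA_DT sorts as minimal.

    Returns (retained primaryid set, duplicates_removed, raw_count).
    Deterministic under any input ordering.
    """
    best: Dict[str, Tuple[tuple, Tuple[int, str], str]] = {}
    raw = 0
    for rec in demo_records:
        raw += 1
        key = (date_sort_key(rec.fda_dt), _pid_key(rec.primaryid))
        cur = best.get(rec.caseid)
        if cur is None or key > (cur[0], cur[1]):
            best[rec.caseid] = (key[0], key[1], rec.primaryid)
    retained = {entry[2] for entry in best.values()}
    return retained, raw - len(retained), raw


def apply_deletions(cases: Dict[str, CaseReport], deletion_lists) -> Tuple[Dict[str, CaseReport], int]:
    """Drop cases whose caseid appears in any deletion list.

    Unknown caseids in the lists are ignored (and counted in the log).
    """
    to_delete: Set[str] = set()
    for dl in deletion_lists:
        to_delete |= dl.caseids
    removed = {cid for cid in cases if cid in to_delete}
    ignored = len(to_delete - removed)
    if ignored:
        logger.info("%d deletion-list caseids not present in corpus", ignored)
    kept = {cid: c for cid, c in cases.items() if cid not in removed}
    return kept, len(removed)


def assemble_cases(bundles: Sequence[QuarterBundle],
                   retained_primaryids: Set[str]) -> Dict[str, CaseReport]:
    """Join DRUG/REAC/OUTC/THER records onto the retained DEMO versions.

    Returns caseid -> CaseReport with verbatim (not yet standardized) drugs.
    """
    cases: Dict[str, CaseReport] = {}
    by_pid: Dict[str, CaseReport] = {}
    for bundle in bundles:
        for rec in bundle.demo:
            if rec.primaryid not in retained_primaryids:
                continue
            age_years, _ = normalize_age(rec.age_value, rec.age_unit)
            case = CaseReport(
                caseid=rec.caseid,
                primaryid=rec.primaryid,
                fda_dt=rec.fda_dt,
                event_dt=rec.event_dt,
                sex=rec.sex,
                age_years=age_years,
                country=rec.reporter_country,
                reporter=reporter_category(rec.occupation_code),
            )
            cases[rec.caseid] = case
            by_pid[rec.primaryid] = case

    # therapy starts keyed by (primaryid, drug_seq); earliest full date wins
    starts: Dict[Tuple[str, str], PartialDate] = {}
    for bundle in bundles:
        for t in bundle.ther:
            if t.start_dt is None or not t.start_dt.is_full:
                continue
            key = (t.primaryid, t.drug_seq)
            cur = starts.get(key)
            if cur is None or t.start_dt.sort_key() < cur.sort_key():
                starts[key] = t.start_dt

    for bundle in bundles:
        for d in bundle.drug:
            case = by_pid.get(d.primaryid)
            if case is None:
                continue
            use = DrugUse(name=d.drugname_verbatim,
                          roles={d.role_code} if d.role_code else set(),
                          start_dt=starts.get((d.primaryid, d.drug_seq)))
            case.drugs.append(use)
        for r in bundle.reac:
            case = by_pid.get(r.primaryid)
            if case is not None:
                case.reactions.append(Reaction(r.pt_code, r.pt_name))
        for o in bundle.outc:
            case = by_pid.get(o.primaryid)
            if case is not None:
                case.outcomes.add(o.outcome_code)
    return cases


def standardize(cases: Dict[str, CaseReport], term_map: TermMap):
    """Standardize drug names and annotate reactions with PT/SOC.

    Within a case the same standardized ingredient is merged: roles are
    unioned and the earliest full-precision start date is kept, so a
    combination product never counts twice in a contingency table.
    Returns (cases, unmapped-name Counter).
    """
    unmapped: Counter = Counter()
    for case in cases.values():
        merged: Dict[str, DrugUse] = {}
        for use in case.drugs:
            std, ok = term_map.map_drug(use.name)
            if not ok:
                unmapped[use.name] += 1
            slot = merged.get(std)
            if slot is None:
                merged[std] = DrugUse(name=std, roles=set(use.roles),
                                      start_dt=use.start_dt, mapped=ok)
            else:
                slot.roles |= use.roles
                if use.start_dt is not None and (
                        slot.start_dt is None
                        or use.start_dt.sort_key() < slot.start_dt.sort_key()):
                    slot.start_dt = use.start_dt
        case.drugs = list(merged.values())
        for reaction in case.reactions:
            name, soc = term_map.map_pt(reaction.pt_code)
            if name is not None:
                reaction.pt_name = reaction.pt_name or name
                reaction.soc_name = soc
    return cases, unmapped


def select_target_cases(cases: Dict[str, CaseReport],
                        target_pt_codes: Iterable[str]) -> Dict[str, CaseReport]:
    """Cases listing at least one target preferred term (each counted once)."""
    targets = {str(code) for code in target_pt_codes}
    if not targets:
        raise ValueError("target PT set must be non-empty")
    return {cid: c for cid, c in cases.items() if c.pt_codes() & targets}


def filter_roles(cases: Dict[str, CaseReport], roles: Optional[Set[str]]) -> Dict[str, CaseReport]:
    """Restrict each case's drug list to the given role codes (e.g. {PS, SS}).

    Cases left with no drugs are retained (they still contribute to the
    corpus denominator). roles=None means no filtering.
    """
    if roles is None:
        return cases
    roles = {r.upper() for r in roles}
    out: Dict[str, CaseReport] = {}
    for cid, case in cases.items():
        kept = [d for d in case.drugs if d.roles & roles]
        clone = CaseReport(**{**case.__dict__, "drugs": kept})
        out[cid] = clone
    return out


def build_corpus(bundles: Sequence[QuarterBundle], term_map: TermMap,
                 target_pt_codes: Iterable[str] = ("10001052",),
                 roles: Optional[Set[str]] = None):
    """Full cleaning chain: dedup -> deletions -> join -> standardize.

    Returns (cases, target_cases, FlowCounts, unmapped Counter).
    """
    all_demo = [rec for b in bundles for rec in b.demo]
    retained, dups, raw = deduplicate(all_demo)
    cases = assemble_cases(bundles, retained)
    deletion_lists = [b.deletions for b in bundles if b.deletions is not None]
    cases, deleted = apply_deletions(cases, deletion_lists)
    cases, unmapped = standardize(cases, term_map)
    if roles is not None:
        cases = filter_roles(cases, roles)
    target = select_target_cases(cases, target_pt_codes)
    flow = FlowCounts(raw_reports=raw, duplicates_removed=dups,
                      deleted_by_list=deleted, unique_cases=len(cases),
                      target_cases=len(target))
    flow.check()
    return cases, target, flow, unmapped
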