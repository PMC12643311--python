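"""Reading and writing FAERS quarterly ASCII extracts.

FAERS quarters ship as "$"-delimited text tables (DEMO, DRUG, REAC, OUTC,
THER) with a header line, plus — from 2019Q1 — a deletion-report list of
CASEIDs to purge. The delimiter admits no quoting or escaping, so parsing
is a plain split; rows with the wrong field count are skipped and logged
(or raised in strict mode). Files are decoded as UTF-8 with a Latin-1
fallback, matching the bytes actually found in the published extracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Union

from faerspv.dates import PartialDate, parse_date

logger = logging.getLogger(__name__)

DELIMITER = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER")

#: Column layout of each table kind (names follow the FAERS ASCII headers).
TABLE_COLUMNS = {
    "DEMO": (
        "primaryid", "caseid", "fda_dt", "event_dt", "sex",
        "age", "age_cod", "reporter_country", "occp_cod",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt_code", "pt_name"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt"),
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
ROLE_CODES = ("PS", "SS", "C", "I")
AGE_UNITS = ("DEC", "YR", "MON", "WK", "DY", "HR")


class ParseError(ValueError):
    """Fatal parse failure (strict mode or unreadable file)."""


@dataclass
class RawDemoRecord:
    primaryid: str
    caseid: str
    fda_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate]
    sex: Optional[str]
    age_value: Optional[float]
    age_unit: Optional[str]
    reporter_country: Optional[str]
    occupation_code: Optional[str]

    @property
    def report_year(self) -> Optional[int]:
        return self.fda_dt.year if self.fda_dt is not None else None


@dataclass
class RawDrugRecord:
    primaryid: str
    drug_seq: str
    role_code: Optional[str]
    drugname_verbatim: str


@dataclass
class RawReacRecord:
    primaryid: str
    pt_code: Optional[str]
    pt_name: Optional[str]


@dataclass
class RawOutcRecord:
    primaryid: str
    outcome_code: str


@dataclass
class RawTherRecord:
    primaryid: str
    drug_seq: str
    start_dt: Optional[PartialDate]
    end_dt: Optional[PartialDate]


@dataclass
class DeletionList:
    caseids: Set[str]
    quarter_label: str = ""

    def __len__(self) -> int:
        return len(self.caseids)


@dataclass
class ParseReport:
    """Line accounting for one file: total = kept + malformed + header."""

    path: str
    table_kind: str
    lines_total: int = 0
    records_kept: int = 0
    malformed_skipped: int = 0
    substitutions: int = 0  # fields replaced by missing within kept records

    def check(self) -> None:
        assert self.lines_total == self.records_kept + self.malformed_skipped + 1


@dataclass
class QuarterBundle:
    """One quarter's five tables plus its (optional) deletion list."""

    quarter_label: str
    demo: List[RawDemoRecord] = field(default_factory=list)
    drug: List[RawDrugRecord] = field(default_factory=list)
    reac: List[RawReacRecord] = field(default_factory=list)
    outc: List[RawOutcRecord] = field(default_factory=list)
    ther: List[RawTherRecord] = field(default_factory=list)
    deletions: Optional[DeletionList] = None

    def orphan_count(self) -> int:
        """Primaryids in child tables that join no DEMO record."""
        known = {r.primaryid for r in self.demo}
        orphans = set()
        for coll in (self.drug, self.reac, self.outc, self.ther):
            for rec in coll:
                if rec.primaryid not in known:
                    orphans.add(rec.primaryid)
        return len(orphans)


def _read_text(path: Union[str, Path]) -> List[str]:
    data = Path(path).read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        text = data.decode("latin-1")
    return text.splitlines()


def _opt(s: str) -> Optional[str]:
    s = s.strip()
    return s if s else None


def _parse_demo(fields: Sequence[str], report: ParseReport) -> Optional[RawDemoRecord]:
    primaryid = fields[0].strip()
    caseid = fields[1].strip()
    if not primaryid or not caseid:
        return None
    fda_dt = parse_date(fields[2])
    if fields[2].strip() and fda_dt is None:
        report.substitutions += 1
    event_dt = parse_date(fields[3])
    if fields[3].strip() and event_dt is None:
        report.substitutions += 1
    sex = _opt(fields[4])
    if sex is not None and sex.upper() not in ("F", "M"):
        sex = None  # UNK and other codes collapse to missing
    age_value: Optional[float] = None
    age_raw = fields[5].strip()
    if age_raw:
        try:
            age_value = float(age_raw)
        except ValueError:
            report.substitutions += 1
        else:
            if age_value < 0:
                age_value = None
                report.substitutions += 1
    age_unit = _opt(fields[6])
    if age_unit is not None:
        age_unit = age_unit.upper()
        if age_unit not in AGE_UNITS:
            age_unit = None
            report.substitutions += 1
    return RawDemoRecord(
        primaryid=primaryid,
        caseid=caseid,
        fda_dt=fda_dt,
        event_dt=event_dt,
        sex=sex.upper() if sex else None,
        age_value=age_value,
        age_unit=age_unit,
        reporter_country=_opt(fields[7]),
        occupation_code=_opt(fields[8]),
    )


def _parse_drug(fields: Sequence[str], report: ParseReport) -> Optional[RawDrugRecord]:
    primaryid = fields[0].strip()
    drugname = fields[3].strip()
    if not primaryid or not drugname:
        return None
    role = _opt(fields[2])
    if role is not None:
        role = role.upper()
        if role not in ROLE_CODES:
            role = None
            report.substitutions += 1
    return RawDrugRecord(primaryid, fields[1].strip(), role, drugname)


def _parse_reac(fields: Sequence[str], report: ParseReport) -> Optional[RawReacRecord]:
    primaryid = fields[0].strip()
    pt_code = _opt(fields[1])
    pt_name = _opt(fields[2])
    if not primaryid or (pt_code is None and pt_name is None):
        return None
    return RawReacRecord(primaryid, pt_code, pt_name)


def _parse_outc(fields: Sequence[str], report: ParseReport) -> Optional[RawOutcRecord]:
    primaryid = fields[0].strip()
    code = fields[1].strip().upper()
    if not primaryid or code not in OUTCOME_CODES:
        return None
    return RawOutcRecord(primaryid, code)


def _parse_ther(fields: Sequence[str], report: ParseReport) -> Optional[RawTherRecord]:
    primaryid = fields[0].strip()
    if not primaryid:
        return None
    start = parse_date(fields[2])
    if fields[2].strip() and start is None:
        report.substitutions += 1
    end = parse_date(fields[3])
    # end < start occurs in real data; the record is retained as-is.
    return RawTherRecord(primaryid, fields[1].strip(), start, end)


_PARSERS = {
    "DEMO": _parse_demo,
    "DRUG": _parse_drug,
    "REAC": _parse_reac,
    "OUTC": _parse_outc,
    "THER": _parse_ther,
}


def read_table(path: Union[str, Path], table_kind: str, strict: bool = False):
    """Read one FAERS table file into typed records plus a ParseReport.

    Parameters
    ----------
    path : file to read ("$"-delimited, header line first).
    table_kind : one of DEMO, DRUG, REAC, OUTC, THER.
    strict : raise on the first malformed line instead of skip-and-log.

    Returns
    -------
    (records, report) : list of typed records and the line accounting.
    """
    kind = table_kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    try:
        lines = _read_text(path)
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc

    ncols = len(TABLE_COLUMNS[kind])
    parser = _PARSERS[kind]
    report = ParseReport(path=str(path), table_kind=kind, lines_total=len(lines))
    records = []
    for lineno, line in enumerate(lines):
        if lineno == 0:  # header
            continue
        fields = line.split(DELIMITER)
        rec = parser(fields, report) if len(fields) == ncols else None
        if rec is None:
            if strict:
                raise ParseError(f"{path}:{lineno + 1}: malformed {kind} row: {line!r}")
            report.malformed_skipped += 1
            logger.debug("%s:%d malformed %s row skipped", path, lineno + 1, kind)
            continue
        records.append(rec)
    report.records_kept = len(records)
    report.check()
    return records, report


def read_deletion_list(path: Union[str, Path], quarter_label: str = "") -> DeletionList:
    """Read a deletion-report list: one CASEID per line, header tolerated."""
    lines = _read_text(path)
    caseids: Set[str] = set()
    for lineno, line in enumerate(lines):
        s = line.strip().strip(DELIMITER)
        if not s:
            continue
        if lineno == 0 and not s.isdigit():
            continue  # header such as "caseid"
        caseids.add(s)
    if not caseids:
        logger.warning("deletion list %s is empty", path)
    return DeletionList(caseids=caseids, quarter_label=quarter_label)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _demo_row(r: RawDemoRecord) -> List[str]:
    return [r.primaryid, r.caseid, _fmt(r.fda_dt), _fmt(r.event_dt), _fmt(r.sex),
            _fmt(r.age_value), _fmt(r.age_unit), _fmt(r.reporter_country),
            _fmt(r.occupation_code)]


def _drug_row(r: RawDrugRecord) -> List[str]:
    return [r.primaryid, r.drug_seq, _fmt(r.role_code), r.drugname_verbatim]


def _reac_row(r: RawReacRecord) -> List[str]:
    return [r.primaryid, _fmt(r.pt_code), _fmt(r.pt_name)]


def _outc_row(r: RawOutcRecord) -> List[str]:
    return [r.primaryid, r.outcome_code]


def _ther_row(r: RawTherRecord) -> List[str]:
    return [r.primaryid, r.drug_seq, _fmt(r.start_dt), _fmt(r.end_dt)]


_WRITERS = {
    "DEMO": _demo_row,
    "DRUG": _drug_row,
    "REAC": _reac_row,
    "OUTC": _outc_row,
    "THER": _ther_row,
}


def write_table(records: Iterable, path: Union[str, Path], table_kind: str) -> None:
    """Write records in the FAERS dialect; read_table round-trips them."""
    kind = table_kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    row_fn = _WRITERS[kind]
    lines = [DELIMITER.join(TABLE_COLUMNS[kind])]
    lines.extend(DELIMITER.join(row_fn(r)) for r in records)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_deletion_list(deletions: DeletionList, path: Union[str, Path]) -> None:
    lines = ["caseid"] + sorted(deletions.caseids, key=lambda s: (len(s), s))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_bundle(bundle: QuarterBundle, directory: Union[str, Path]) -> dict:
    """Write a quarter bundle as DEMO<label>.txt etc.; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label = bundle.quarter_label
    paths = {}
    for kind, coll in (("DEMO", bundle.demo), ("DRUG", bundle.drug),
                       ("REAC", bundle.reac), ("OUTC", bundle.outc),
                       ("THER", bundle.ther)):
        p = directory / f"{kind}{label}.txt"
        write_table(coll, p, kind)
        paths[kind] = p
    if bundle.deletions is not None:
        p = directory / f"DELETED{label}.txt"
        write_deletion_list(bundle.deletions, p)
        paths["DELETED"] = p
    return paths


def read_bundle(directory: Union[str, Path], quarter_label: str,
                strict: bool = False) -> QuarterBundle:
    """Read a quarter written by write_bundle (DEMO<label>.txt naming)."""
    directory = Path(directory)
    bundle = QuarterBundle(quarter_label=quarter_label)
    for kind, attr in (("DEMO", "demo"), ("DRUG", "drug"), ("REAC", "reac"),
                       ("OUTC", "outc"), ("THER", "ther")):
        p = directory / f"{kind}{quarter_label}.txt"
        if p.exists():
            records, _ = read_table(p, kind, strict=strict)
            setattr(bundle, attr, records)
    deleted = directory / f"DELETED{quarter_label}.txt"
    if deleted.exists():
        bundle.deletions = read_deletion_list(deleted, quarter_label)
    return bundle
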