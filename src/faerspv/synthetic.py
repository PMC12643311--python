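"""Synthetic FAERS-format data with a planted ground truth.

The generator emits the same multi-table quarterly dialect the reader
consumes — DEMO/DRUG/REAC/OUTC/THER plus a deletion list — together with a
manifest of everything that was planted: per-drug relative reporting rates
for the target event, duplicate case versions, deleted caseids, and true
onset intervals. Every pipeline stage can therefore be checked against a
known answer without downloading anything.

Cases are drawn independently. Drug exposures are Bernoulli per catalog
drug; the target event occurs with probability ``baseline * max(RR over
exposed drugs)`` (the max rule keeps each drug's marginal relative rate
interpretable under polypharmacy). Exposed cases that develop the event
receive an onset interval drawn from the causing drug's Weibull onset
distribution; a configurable fraction of cases lose their dates or violate
date ordering, emulating the heavy missingness of real onset data.

Demographic category distributions default to those observed in a large
drug-induced ARDS case series (sex 46.69% male / 42.81% female / 10.50%
unspecified, and so on), so descriptive output resembles real profiles.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from faerspv.casestore import TermMap
from faerspv.dates import PartialDate
from faerspv.io import (
    DeletionList,
    QuarterBundle,
    RawDemoRecord,
    RawDrugRecord,
    RawOutcRecord,
    RawReacRecord,
    RawTherRecord,
    write_bundle,
)

TARGET_PT_CODE = "10001052"
TARGET_PT_NAME = "Acute respiratory distress syndrome"
TARGET_SOC = "Respiratory, thoracic and mediastinal disorders"

#: Synthetic non-target preferred terms (codes are stand-ins, not MedDRA).
OTHER_PTS = [
    ("90000001", "Headache", "Nervous system disorders"),
    ("90000002", "Nausea", "Gastrointestinal disorders"),
    ("90000003", "Rash", "Skin and subcutaneous tissue disorders"),
    ("90000004", "Pyrexia", "General disorders"),
    ("90000005", "Dizziness", "Nervous system disorders"),
    ("90000006", "Fatigue", "General disorders"),
    ("90000007", "Dyspnoea", "Respiratory, thoracic and mediastinal disorders"),
    ("90000008", "Vomiting", "Gastrointestinal disorders"),
]

_VERBATIM_SUFFIXES = ["", " CAP", " TAB", " 100MG"]


@dataclass
class DrugSpec:
    """One catalog drug: marginal exposure probability, relative reporting
    rate for the target event, and Weibull onset parameters (days)."""

    name: str
    exposure_prob: float
    rr: float = 1.0
    onset_scale: float = 50.0
    onset_shape: float = 0.7


@dataclass
class SyntheticConfig:
    n_cases: int
    seed: int
    drugs: List[DrugSpec] = field(default_factory=list)
    baseline_event_prob: float = 0.005
    duplicate_rate: float = 0.05
    deletion_fraction: float = 0.005
    missing_date_fraction: float = 0.60
    negative_tto_fraction: float = 0.05
    quarter_label: str = "24Q1"
    # category distributions: (labels, probabilities); None label = missing
    sex_dist: Tuple[Tuple[Optional[str], ...], Tuple[float, ...]] = (
        ("M", "F", None), (0.4669, 0.4281, 0.1050))
    age_band_dist: Tuple[Tuple[Optional[str], ...], Tuple[float, ...]] = (
        ("<18", "18-44", "45-64", ">=65", None),
        (0.0829, 0.1960, 0.2702, 0.2601, 0.1908))
    reporter_dist: Tuple[Tuple[Optional[str], ...], Tuple[float, ...]] = (
        ("MD", "PH", "OT", "CN", "LW", None),
        (0.4054, 0.2159, 0.2179, 0.0841, 0.0049, 0.0718))
    country_dist: Tuple[Tuple[Optional[str], ...], Tuple[float, ...]] = (
        ("US", "FR", "JP", "OTHER"), (0.3786, 0.1364, 0.0865, 0.3985))
    outcome_probs: Dict[str, float] = field(default_factory=lambda: {
        "HO": 0.6504, "DE": 0.5121, "OT": 0.5215, "LT": 0.3064,
        "DS": 0.0195, "RI": 0.0106, "CA": 0.0031})

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        for p in (self.baseline_event_prob, self.duplicate_rate,
                  self.deletion_fraction, self.missing_date_fraction,
                  self.negative_tto_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for d in self.drugs:
            if not 0.0 <= d.exposure_prob <= 1.0:
                raise ValueError(f"{d.name}: exposure_prob outside [0, 1]")
            if d.rr <= 0:
                raise ValueError(f"{d.name}: RR must be > 0")
            if self.baseline_event_prob * d.rr > 1.0:
                raise ValueError(
                    f"infeasible config: baseline * RR = "
                    f"{self.baseline_event_prob * d.rr:.3f} > 1 for {d.name}")
        for labels, probs in (self.sex_dist, self.age_band_dist,
                              self.reporter_dist, self.country_dist):
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError("category probabilities must sum to 1")


def default_config(n_cases: int = 50_000, seed: int = 0,
                   n_background: int = 20,
                   signal_rr: float = 10.0) -> SyntheticConfig:
    """Study-condition defaults: one planted signal drug at RR = 10 over a
    background of RR = 1 drugs, baseline target-event rate 0.005."""
    drugs = [DrugSpec("SIGNALOL", exposure_prob=0.02, rr=signal_rr,
                      onset_scale=50.0, onset_shape=0.7)]
    for i in range(n_background):
        drugs.append(DrugSpec(f"PLACEBEX{i + 1:02d}", exposure_prob=0.05,
                              rr=1.0, onset_scale=50.0, onset_shape=0.7))
    return SyntheticConfig(n_cases=n_cases, seed=seed, drugs=drugs)


@dataclass
class CaseTruth:
    caseid: str
    primaryid: str
    exposures: List[str]
    is_target: bool
    onset_days: Optional[int] = None  # true interval when dates are valid


@dataclass
class GroundTruth:
    drug_rr: Dict[str, float]
    duplicate_pairs: List[Tuple[str, str]]  # (original pid, duplicate pid)
    deleted_caseids: List[str]
    cases: List[CaseTruth]

    def analysis_cases(self) -> List[CaseTruth]:
        deleted = set(self.deleted_caseids)
        return [c for c in self.cases if c.caseid not in deleted]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "drug_rr": self.drug_rr,
            "duplicate_pairs": self.duplicate_pairs,
            "deleted_caseids": self.deleted_caseids,
            "cases": [asdict(c) for c in self.cases],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            drug_rr=payload["drug_rr"],
            duplicate_pairs=[tuple(p) for p in payload["duplicate_pairs"]],
            deleted_caseids=payload["deleted_caseids"],
            cases=[CaseTruth(**c) for c in payload["cases"]],
        )


def _pdate(d: datetime.date) -> PartialDate:
    return PartialDate(d.year, d.month, d.day)


def _choose(rng: np.random.Generator, dist) -> Optional[str]:
    labels, probs = dist
    idx = rng.choice(len(labels), p=np.asarray(probs) / sum(probs))
    return labels[int(idx)]


_AGE_RANGES = {"<18": (0, 17), "18-44": (18, 44), "45-64": (45, 64),
               ">=65": (65, 100)}

_EPOCH = datetime.date(2015, 1, 1)
_SPAN_DAYS = 9 * 365  # therapy anchors through 2023


def generate(config: SyntheticConfig) -> Tuple[QuarterBundle, GroundTruth]:
    """Build one quarter bundle plus its ground-truth manifest.

    All randomness flows from ``config.seed``; the same config yields the
    same records (and, through ``generate_files``, byte-identical files).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bundle = QuarterBundle(quarter_label=config.quarter_label)
    truth = GroundTruth(drug_rr={d.name: d.rr for d in config.drugs},
                        duplicate_pairs=[], deleted_caseids=[], cases=[])
    specs = config.drugs
    exposure_probs = np.array([d.exposure_prob for d in specs])

    for i in range(config.n_cases):
        caseid = str(100_000 + i)
        primaryid = caseid + "1"
        exposed_idx = np.nonzero(rng.random(len(specs)) < exposure_probs)[0]
        if len(exposed_idx) == 0:
            # every report lists at least one drug; the filler is neutral
            exposures = ["FILLERENE"]
            max_rr = 1.0
            onset_spec = None
        else:
            exposures = [specs[j].name for j in exposed_idx]
            rrs = [specs[j].rr for j in exposed_idx]
            k = int(np.argmax(rrs))
            max_rr = rrs[k]
            onset_spec = specs[exposed_idx[k]]
        p_event = min(config.baseline_event_prob * max_rr, 1.0)
        is_target = bool(rng.random() < p_event)

        start = _EPOCH + datetime.timedelta(days=int(rng.integers(0, _SPAN_DAYS)))
        if is_target and onset_spec is not None:
            raw_onset = onset_spec.onset_scale * rng.weibull(onset_spec.onset_shape)
        else:
            raw_onset = float(rng.integers(0, 365))
        onset_days = int(round(raw_onset))
        event = start + datetime.timedelta(days=onset_days)

        # degrade dates: missing, or planted negative interval
        u = rng.random()
        event_dt: Optional[PartialDate] = _pdate(event)
        start_dates: Dict[str, Optional[PartialDate]] = {
            name: _pdate(start) for name in exposures}
        truth_onset: Optional[int] = onset_days
        if u < config.missing_date_fraction:
            if rng.random() < 0.5:
                event_dt = None
            else:
                start_dates = {name: None for name in exposures}
            truth_onset = None
        elif u < config.missing_date_fraction + config.negative_tto_fraction:
            event_dt = _pdate(start - datetime.timedelta(
                days=int(rng.integers(1, 60))))
            truth_onset = None

        fda = event + datetime.timedelta(days=int(rng.integers(1, 180)))
        sex = _choose(rng, config.sex_dist)
        band = _choose(rng, config.age_band_dist)
        if band is None:
            age_value, age_unit = None, None
        else:
            lo, hi = _AGE_RANGES[band]
            age_value = float(rng.integers(lo, hi + 1))
            age_unit = "YR"
        occp = _choose(rng, config.reporter_dist)
        country = _choose(rng, config.country_dist)

        bundle.demo.append(RawDemoRecord(
            primaryid=primaryid, caseid=caseid, fda_dt=_pdate(fda),
            event_dt=event_dt, sex=sex, age_value=age_value,
            age_unit=age_unit, reporter_country=country,
            occupation_code=occp))

        versions = [primaryid]
        if rng.random() < config.duplicate_rate:
            dup_pid = caseid + "2"
            dup_fda = fda + datetime.timedelta(days=int(rng.integers(1, 90)))
            bundle.demo.append(RawDemoRecord(
                primaryid=dup_pid, caseid=caseid, fda_dt=_pdate(dup_fda),
                event_dt=event_dt, sex=sex, age_value=age_value,
                age_unit=age_unit, reporter_country=country,
                occupation_code=occp))
            truth.duplicate_pairs.append((primaryid, dup_pid))
            versions.append(dup_pid)
            primaryid = dup_pid  # version retained after dedup

        roles = ["PS"] + ["SS", "C", "I"] * 4
        reactions: List[Tuple[Optional[str], str]] = []
        if is_target:
            reactions.append((TARGET_PT_CODE, TARGET_PT_NAME))
        n_other = int(rng.integers(1, 3))
        for j in rng.choice(len(OTHER_PTS), size=n_other, replace=False):
            code, name, _ = OTHER_PTS[int(j)]
            reactions.append((code, name))
        outcomes = [code for code, p in sorted(config.outcome_probs.items())
                    if rng.random() < p]
        suffix_idx = int(rng.integers(0, len(_VERBATIM_SUFFIXES)))

        for pid in versions:  # every version carries its own child rows
            for seq, name in enumerate(exposures, start=1):
                verbatim = name + _VERBATIM_SUFFIXES[(suffix_idx + seq) %
                                                     len(_VERBATIM_SUFFIXES)]
                bundle.drug.append(RawDrugRecord(
                    primaryid=pid, drug_seq=str(seq),
                    role_code=roles[(seq - 1) % len(roles)],
                    drugname_verbatim=verbatim))
                sd = start_dates[name]
                bundle.ther.append(RawTherRecord(
                    primaryid=pid, drug_seq=str(seq), start_dt=sd,
                    end_dt=None))
            for code, name in reactions:
                bundle.reac.append(RawReacRecord(pid, code, name))
            for code in outcomes:
                bundle.outc.append(RawOutcRecord(pid, code))

        truth.cases.append(CaseTruth(
            caseid=caseid, primaryid=primaryid, exposures=exposures,
            is_target=is_target,
            onset_days=truth_onset if is_target else None))

    if config.deletion_fraction > 0:
        n_del = int(round(config.deletion_fraction * config.n_cases))
        if n_del > 0:
            idx = rng.choice(config.n_cases, size=n_del, replace=False)
            deleted = sorted(str(100_000 + int(i)) for i in idx)
            truth.deleted_caseids = deleted
            bundle.deletions = DeletionList(set(deleted), config.quarter_label)
    return bundle, truth


def generate_files(config: SyntheticConfig, directory: Union[str, Path]):
    """Generate and write a quarter to disk plus the truth manifest JSON."""
    bundle, truth = generate(config)
    paths = write_bundle(bundle, directory)
    manifest = Path(directory) / "ground_truth.json"
    truth.to_json(manifest)
    paths["TRUTH"] = manifest
    return paths, truth


def default_term_map(config: Optional[SyntheticConfig] = None) -> TermMap:
    """TermMap covering every PT and drug verbatim the generator can emit."""
    tm = TermMap()
    tm.pt_map[TARGET_PT_CODE] = (TARGET_PT_NAME, TARGET_SOC)
    for code, name, soc in OTHER_PTS:
        tm.pt_map[code] = (name, soc)
    names = ([d.name for d in config.drugs] if config is not None
             else [d.name for d in default_config(10, 0).drugs])
    names.append("FILLERENE")
    for name in names:
        canonical = name.capitalize()
        for suffix in _VERBATIM_SUFFIXES:
            tm.drug_map[TermMap.normalize_verbatim(name + suffix)] = canonical
    return tm


# ---------------------------------------------------------------------------
# Hand-built micro-fixtures with enumerable answers
# ---------------------------------------------------------------------------

def _demo(pid, cid, fda, event=None, sex="F", age=50.0, unit="YR",
          country="US", occp="MD"):
    from faerspv.dates import parse_date
    return RawDemoRecord(pid, cid, parse_date(fda),
                         parse_date(event) if event else None,
                         sex, age, unit, country, occp)


def make_fixture(name: str) -> QuarterBundle:
    """Deterministic micro-corpora used in unit tests.

    - "four-case": 2 cases list drug X (one with the target PT), 2 do not
      (one with the target PT) -> X's table is (1, 1, 1, 1).
    - "dup-tie": one caseid with two versions sharing FDA_DT; dedup must
      keep the higher primaryid (72).
    - "neg-tto": one case whose therapy starts after the event date.
    """
    b = QuarterBundle(quarter_label="fix")
    if name == "four-case":
        for i, (has_x, has_t) in enumerate(
                [(True, True), (True, False), (False, True), (False, False)]):
            pid, cid = f"{10 + i}1", str(10 + i)
            b.demo.append(_demo(pid, cid, "20240101", "20240101"))
            drug = "DRUGX" if has_x else "DRUGY"
            b.drug.append(RawDrugRecord(pid, "1", "PS", drug))
            if has_t:
                b.reac.append(RawReacRecord(pid, TARGET_PT_CODE, TARGET_PT_NAME))
            else:
                b.reac.append(RawReacRecord(pid, "90000001", "Headache"))
        return b
    if name == "dup-tie":
        b.demo.append(_demo("71", "7", "20200101", "20200101"))
        b.demo.append(_demo("72", "7", "20200101", "20200101"))
        for pid in ("71", "72"):
            b.drug.append(RawDrugRecord(pid, "1", "PS", "DRUGX"))
            b.reac.append(RawReacRecord(pid, TARGET_PT_CODE, TARGET_PT_NAME))
        return b
    if name == "neg-tto":
        pid, cid = "81", "8"
        b.demo.append(_demo(pid, cid, "20240301", "20240110"))
        b.drug.append(RawDrugRecord(pid, "1", "PS", "DRUGX"))
        b.ther.append(RawTherRecord(pid, "1", PartialDate(2024, 2, 1), None))
        b.reac.append(RawReacRecord(pid, TARGET_PT_CODE, TARGET_PT_NAME))
        return b
    raise ValueError(f"unknown fixture: {name!r}")


def fixture_term_map() -> TermMap:
    tm = TermMap()
    tm.pt_map[TARGET_PT_CODE] = (TARGET_PT_NAME, TARGET_SOC)
    tm.pt_map["90000001"] = ("Headache", "Nervous system disorders")
    tm.drug_map["DRUGX"] = "Drugx"
    tm.drug_map["DRUGY"] = "Drugy"
    return tm
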