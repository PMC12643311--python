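"""Shared settings for the numbered analysis scripts.

One synthetic study is analysed throughout: 50,000 cases at the study
conditions (baseline target-event rate 0.005; one drug planted at
relative rate 10 over twenty background drugs at relative rate 1), with
5% duplicate versions, a deletion list covering 0.5% of cases, and 65% of
onset intervals lost to missing dates or date-order violations.
"""

from pathlib import Path

from faerspv.casestore import build_corpus
from faerspv.synthetic import default_config, default_term_map, generate

SEED = 11
N_CASES = 50_000
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "synthetic_quarter"
TARGET_PT = ("10001052",)


def study_config():
    return default_config(n_cases=N_CASES, seed=SEED)


def study_corpus():
    """Generate the study bundle in memory and clean it end to end."""
    config = study_config()
    bundle, truth = generate(config)
    cases, target, flow, unmapped = build_corpus(
        [bundle], default_term_map(config), TARGET_PT)
    return {"config": config, "bundle": bundle, "truth": truth,
            "cases": cases, "target": target, "flow": flow,
            "unmapped": unmapped}
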