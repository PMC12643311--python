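import pytest

from faerspv.casestore import build_corpus
from faerspv.synthetic import default_config, default_term_map, generate


@pytest.fixture(scope="session")
def study_scale():
    """One 50,000-case synthetic corpus at the study conditions:
    baseline target-event rate 0.005, one drug planted at RR = 10 over
    20 background drugs at RR = 1. Shared across tests for speed."""
    config = default_config(n_cases=50_000, seed=1)
    bundle, truth = generate(config)
    cases, target, flow, unmapped = build_corpus(
        [bundle], default_term_map(config))
    return {"config": config, "bundle": bundle, "truth": truth,
            "cases": cases, "target": target, "flow": flow}


@pytest.fixture(scope="session")
def small_corpus():
    """A 2,000-case corpus with no duplicates/deletions/missing dates,
    small enough for exhaustive recounting in property tests."""
    config = default_config(n_cases=2_000, seed=42, n_background=5)
    config.duplicate_rate = 0.0
    config.deletion_fraction = 0.0
    config.missing_date_fraction = 0.0
    config.negative_tto_fraction = 0.0
    config.baseline_event_prob = 0.05
    bundle, truth = generate(config)
    cases, target, flow, _ = build_corpus([bundle], default_term_map(config))
    return {"config": config, "truth": truth, "cases": cases,
            "target": target, "flow": flow}
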