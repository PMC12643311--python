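"""Generate the synthetic FAERS study quarter and summarize what was planted.

Writes the five "$"-delimited tables plus the deletion list and
ground-truth manifest under scratch/ (regenerable, not part of the
deliverable) and a small per-drug truth summary under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, SCRATCH, study_config
from faerspv.synthetic import generate_files

def main():
    config = study_config()
    paths, truth = generate_files(config, SCRATCH)
    print(f"wrote synthetic quarter to {SCRATCH}:")
    for kind, p in sorted(paths.items()):
        print(f"  {kind:8s} {Path(p).stat().st_size / 1e6:6.2f} MB")

    exposure = {d.name: 0 for d in config.drugs}
    events = {d.name: 0 for d in config.drugs}
    for ct in truth.cases:
        for name in ct.exposures:
            if name in exposure:
                exposure[name] += 1
                events[name] += ct.is_target
    rows = [{"drug": d.name, "true_rr": d.rr,
             "exposure_prob": d.exposure_prob,
             "n_exposed": exposure[d.name],
             "n_exposed_with_event": events[d.name]}
            for d in config.drugs]
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "simulation_truth.tsv", sep="\t", index=False)

    n_target = sum(ct.is_target for ct in truth.cases)
    print(f"\n{config.n_cases} cases; {n_target} develop the target event "
          f"({100 * n_target / config.n_cases:.2f}%)")
    print(f"planted duplicates: {len(truth.duplicate_pairs)}; "
          f"deletion list: {len(truth.deleted_caseids)} caseids")
    sig = frame[frame.true_rr > 1].iloc[0]
    print(f"signal drug {sig.drug}: RR={sig.true_rr}, "
          f"{sig.n_exposed_with_event}/{sig.n_exposed} exposed cases "
          f"develop the event")
    print(f"wrote {RESULTS / 'simulation_truth.tsv'}")


if __name__ == "__main__":
    main()
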