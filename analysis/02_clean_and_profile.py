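"""Clean the synthetic quarter and profile the target-event cases.

Deduplicates case versions (latest FDA_DT, ties to highest PRIMARYID),
applies the deletion list, standardizes drug names, selects cases
reporting the target preferred term, and writes the flow accounting plus
the descriptive profile (sex, age, year, reporter, outcomes, onset
segmentation) under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import dataclasses

import pandas as pd

from common import RESULTS, study_corpus
from faerspv.pipeline import profile


def main():
    study = study_corpus()
    flow = study["flow"]
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "flow_counts.json").write_text(
        json.dumps(dataclasses.asdict(flow), indent=1))
    print(f"raw reports          {flow.raw_reports}")
    print(f"- duplicate versions {flow.duplicates_removed}")
    print(f"- deletion list      {flow.deleted_by_list}")
    print(f"= unique cases       {flow.unique_cases}")
    print(f"target-event cases   {flow.target_cases} "
          f"({100 * flow.target_cases / flow.unique_cases:.2f}%)")
    flow.check()

    prof = profile(study["target"])
    rows = pd.DataFrame(prof.as_rows(),
                        columns=["section", "label", "count", "percent"])
    rows["percent"] = rows["percent"].round(2)
    rows.to_csv(RESULTS / "profile.tsv", sep="\t", index=False)
    quant = pd.DataFrame([{"block": "age", **prof.age_summary},
                          {"block": "tto", **prof.tto_summary}]).round(2)
    quant.to_csv(RESULTS / "profile_quantitative.tsv", sep="\t", index=False)

    sex = rows[rows.section == "Gender"]
    print("\nsex distribution of target cases:")
    for _, r in sex.iterrows():
        print(f"  {r.label:14s} {int(r['count']):5d} ({r.percent:.2f}%)")
    onset = rows[rows.section == "Time to Onset"]
    missing = onset[onset.label.str.startswith("Missing")]
    print(f"onset interval missing or negative: "
          f"{float(missing.percent.iloc[0]):.2f}% of target cases")
    print(f"wrote {RESULTS / 'profile.tsv'}")


if __name__ == "__main__":
    main()
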