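"""Desk-scale consistency checks against a published ARDS signal table.

The published study reports, per drug, the case count a, the database
marginals (15,986 target-event reports among 18,613,992 deduplicated
reports), and the four statistics. Back-solving a+b from the printed EBGM
point estimate reconstructs each full 2x2 table; recomputing PRR,
chi-square and the EBGM lower bound from those cells must then reproduce
the printed values at printed precision — a strong check that the
estimators are implemented exactly as defined.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS
from faerspv.disproportionality import chi_square, ebgm, prr, ror
from faerspv.reconstruct import reconstruct_table
from faerspv.tto import classify_shape_ci

N_EFFECT = 15_986
N_TOTAL = 18_613_992

# drug -> (a, printed EBGM, printed PRR, printed chi2, printed EBGM05)
PUBLISHED = {
    "Mycophenolic Acid": (542, 9.32, 9.61, 4041.35, 8.55),
    "Rituximab": (329, 2.52, 2.55, 304.06, 2.26),
    "Amiodarone": (271, 12.02, 12.21, 2743.91, 10.66),
}

# published Weibull shape CIs with printed failure-type labels
SHAPE_ROWS = [
    ("Rituximab", 0.50, 0.69, "early"),
    ("Oxaliplatin", 0.81, 1.22, "random"),
    ("Daptomycin", 1.06, 1.68, "wearout"),
    ("Melphalan", 1.03, 2.17, "wearout"),
    ("Tacrolimus", 0.34, 0.55, "early"),
    ("Cytarabine", 0.80, 1.33, "random"),
]


def main():
    rows = []
    for drug, (a, e, prr_pub, chi2_pub, ebgm05_pub) in PUBLISHED.items():
        t = reconstruct_table(a, e, N_EFFECT, N_TOTAL)
        rows.append({
            "drug": drug, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "PRR": round(prr(t).value, 2), "PRR_published": prr_pub,
            "chi2": round(chi_square(t), 2), "chi2_published": chi2_pub,
            "EBGM05": round(ebgm(t).low, 2), "EBGM05_published": ebgm05_pub,
            "ROR": round(ror(t).value, 2),
        })
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "reconstructed_signals.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    prr_ok = (frame.PRR == frame.PRR_published).all()
    eb_diff = (frame.EBGM05 - frame.EBGM05_published).abs().max()
    print(f"\nPRR matches published values to 2 decimals: {prr_ok}")
    print(f"largest EBGM05 deviation: {eb_diff:.2f} "
          f"(last printed digit)")
    worst = (frame.chi2 / frame.chi2_published - 1).abs().max()
    print(f"worst chi-square relative deviation: {worst:.5f}")
    print("(printed ROR is known to differ ~0.4% from the back-solved "
          "cells; the published denominator convention is not stated)")

    labels_ok = all(classify_shape_ci(lo, hi) == label
                    for _, lo, hi, label in SHAPE_ROWS)
    print(f"failure-type rule reproduces published labels: {labels_ok}")
    print(f"wrote {RESULTS / 'reconstructed_signals.tsv'}")


if __name__ == "__main__":
    main()
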