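"""Reconstruct a full 2x2 table from published marginal summaries.

Published signal tables typically print, per drug, only the case count
``a``, the database-wide target-event count ``a + c``, the database size
``N`` and point estimates. Because the crude relative reporting ratio
(EBGM as defined here) is ``a N / ((a+c)(a+b))``, the missing drug margin
can be recovered as ``a + b = round(a N / ((a+c) E))`` from the printed
point estimate ``E``, after which b, c, d follow by subtraction. The
reconstructed table reproduces the printed PRR, chi-square and EBGM lower
bound at printed precision, which makes it a desk-scale consistency check
on any implementation of those statistics.
"""

from __future__ import annotations

from faerspv.disproportionality import ContingencyTable


def reconstruct_table(a: int, ebgm_point: float, n_effect: int,
                      n_total: int) -> ContingencyTable:
    """Back-solve (a, b, c, d) from a, EBGM, a+c and N.

    Parameters
    ----------
    a : printed case-report count for the drug-event pair.
    ebgm_point : printed EBGM (relative reporting ratio) point estimate.
    n_effect : a + c, target-event reports database-wide.
    n_total : N, total reports in the database.
    """
    if not 0 < a <= n_effect <= n_total:
        raise ValueError("marginals must satisfy 0 < a <= a+c <= N")
    n_drug = round(a * n_total / (n_effect * ebgm_point))
    if n_drug < a:
        raise ValueError("printed EBGM inconsistent with marginals")
    b = n_drug - a
    c = n_effect - a
    d = n_total - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)
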