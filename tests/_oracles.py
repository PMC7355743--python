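"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive — exact rational arithmetic,
exhaustive enumeration, O(n^2) pair counting — and shares no code with the
implementation it validates.
"""

from fractions import Fraction
from math import comb, exp, log

import numpy as np


def hwe_enum_p(n_rr: int, n_rh: int, n_hh: int) -> float:
    """Exact HWE test p-value by full enumeration in rational arithmetic.

    Conditional on the allele totals, every attainable heterozygote count
    h has probability  C(n, (nr-h)/2, h, (no-h)/2) * 2^h / C(2n, nr)
    (multinomial over genotype configurations); the p-value sums the
    probabilities of all configurations no more probable than observed.
    """
    n = n_rr + n_rh + n_hh
    nr = 2 * n_rr + n_rh
    no = 2 * n_hh + n_rh
    denom = comb(2 * n, nr)
    probs = {}
    h = nr % 2
    while h <= min(nr, no):
        a, b = (nr - h) // 2, (no - h) // 2
        ways = (
            Fraction(
                comb(n, a) * comb(n - a, h) * (2**h),
                denom,
            )
        )
        probs[h] = ways
        h += 2
    total = sum(probs.values())
    probs = {h: v / total for h, v in probs.items()}
    observed = probs[n_rh]
    return float(sum(v for v in probs.values() if v <= observed))


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of case-control pairs ranked correctly
    (ties worth one half), by exhaustive double loop."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def table_2x2_from(exposure, outcome):
    """Counts (a, b, c, d) = (exp&case, exp&ctrl, unexp&case, unexp&ctrl)."""
    exposure = np.asarray(exposure, dtype=int)
    outcome = np.asarray(outcome, dtype=int)
    a = int(((exposure == 1) & (outcome == 1)).sum())
    b = int(((exposure == 1) & (outcome == 0)).sum())
    c = int(((exposure == 0) & (outcome == 1)).sum())
    d = int(((exposure == 0) & (outcome == 0)).sum())
    return a, b, c, d


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    return (a * d) / (b * c)


def woolf_se_2x2(a: int, b: int, c: int, d: int) -> float:
    """Standard error of the log odds ratio, Woolf's formula."""
    return (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
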