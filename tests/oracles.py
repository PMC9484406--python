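"""Independent oracles for the enrichment statistics.

These deliberately avoid the code paths used by the implementation:
the Fisher oracle enumerates the full hypergeometric support and sums
point probabilities directly; the BH oracle is the textbook step-up
written out by hand.
"""

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by exhaustive enumeration.

    With row margins r1 = a+b, r2 = c+d and first-column total k = a+c,
    enumerate every table with those margins and sum the hypergeometric
    point probabilities not exceeding the observed one (relative tolerance
    on the comparison).
    """
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, k - r2), min(r1, k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, k, r1)
    p_obs = hypergeom.pmf(a, n, k, r1)
    return float(pmf[pmf <= p_obs * (1 + rel_tol)].sum())


def bh_step_up_oracle(pvalues) -> list[float]:
    """Textbook Benjamini-Hochberg step-up, returned in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
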