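"""Independent oracles used by the test suite.

These deliberately take different computational routes from the library
code they check (individual-level ANOVA instead of frequency-based
variance components; explicit probability summation instead of closed
tails) so agreement is informative.
"""

from __future__ import annotations

import math

import numpy as np


def wc_fst_anova_oracle(counts1, counts2):
    """Weir & Cockerham theta-hat via the nested ANOVA on individual allele
    indicators (alleles within individuals within populations).

    Expands genotype-class counts into per-individual allele dosages and
    computes mean squares directly; a = (MSP - MSI)/(2 n_c),
    b = (MSI - MSW)/2, c = MSW.
    """
    pops = []
    for hr, het, ha in (counts1, counts2):
        pops.append(np.array([0.0] * hr + [1.0] * het + [2.0] * ha))
    n = np.array([len(g) for g in pops], dtype=float)
    if (n == 0).any() or n.sum() <= 2:
        return (math.nan,) * 4
    r = 2
    p_i = np.array([g.sum() / (2 * len(g)) for g in pops])
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p_i).sum() / n.sum()
    ssp = (2 * n * (p_i - pbar) ** 2).sum()
    ssi = sum(2 * ((g / 2 - p) ** 2).sum() for g, p in zip(pops, p_i))
    ssw = sum(0.5 * float((g == 1).sum()) for g in pops)
    msp = ssp / (r - 1)
    msi = ssi / (n.sum() - r)
    msw = ssw / n.sum()
    a = (msp - msi) / (2 * nc)
    b = (msi - msw) / 2
    c = msw
    denom = a + b + c
    theta = a / denom if denom != 0 else math.nan
    return a, b, c, theta


def binomial_upper_tail_by_summation(n: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by explicit term-by-term summation."""
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * p**j * (1 - p) ** (n - j)
    return min(1.0, total)
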