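"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or O(n^2)
counting, deliberately sharing no code with the implementation it checks.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value via rational enumeration of all
    heterozygote counts compatible with the observed allele totals."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        nr = (rare - h) // 2
        nc = n - h - nr
        weights[h] = Fraction(2**h, factorial(nr) * factorial(h) * factorial(nc))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def pi_pairwise_oracle(dosages) -> float:
    """Mean pairwise allelic difference over all pairs of allele copies."""
    alleles = []
    for d in dosages:
        if d < 0:
            continue
        alleles += [1] * int(d) + [0] * (2 - int(d))
    n = len(alleles)
    diff = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diff += alleles[i] != alleles[j]
    return diff / pairs


def ibs_pair_oracle(gi, gj) -> float:
    """IBS similarity of two dosage vectors by direct per-site counting."""
    num = den = 0.0
    for a, b in zip(gi, gj):
        if a < 0 or b < 0:
            continue
        num += (2 - abs(int(a) - int(b))) / 2
        den += 1
    return num / den


def per_bin_argmax_oracle(positions, scores, lo, hi, n_bins):
    """Best-scoring site index per equal-width positional bin (ties: first)."""
    width = max((hi - lo + 1) / n_bins, 1e-9)
    best = {}
    for i, (p, sc) in enumerate(zip(positions, scores)):
        b = min(int((p - lo) / width), n_bins - 1)
        if b not in best or sc > best[b][0]:
            best[b] = (sc, i)
    return {b: i for b, (sc, i) in best.items()}


def r2_hand_oracle(a, b) -> float:
    """r^2 via the covariance/variance definition, written out longhand."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov * cov / (va * vb)


def mean_sd_oracle(values):
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1))
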