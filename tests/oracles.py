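"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the bitmask oracle
enumerates every breakpoint pattern; the recursive oracle is a top-down
memoized search written without the production DP's prefix-sum machinery;
the binomial tail is summed term by term from factorials.
"""

from functools import lru_cache
from itertools import product
from math import comb

import numpy as np


def pcf_bruteforce_bitmask(x, lam):
    """Optimal PCF objective by enumerating all 2^(n-1) breakpoint patterns."""
    x = np.asarray(x, float)
    n = len(x)
    best = np.inf
    for mask in product([0, 1], repeat=n - 1):
        cuts = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        cost = lam * sum(mask)
        for s, e in zip(cuts[:-1], cuts[1:]):
            seg = x[s:e]
            cost += float(np.sum((seg - seg.mean()) ** 2))
        best = min(best, cost)
    return best


def pcf_bruteforce_recursive(x, lam):
    """Optimal PCF objective by top-down recursion over the first segment."""
    x = tuple(float(v) for v in x)
    n = len(x)

    def sse(s, e):  # sum of squares about the mean of x[s:e]
        seg = x[s:e]
        m = sum(seg) / len(seg)
        return sum((v - m) ** 2 for v in seg)

    @lru_cache(maxsize=None)
    def best(s):
        if s == n:
            return -lam  # cancels the lam charged for a "segment" after the end
        return min(sse(s, e) + lam + best(e) for e in range(s + 1, n + 1))

    return best(0)


def binomial_upper_tail(k, n, p):
    """P[Bin(n, p) >= k] summed term by term."""
    return sum(comb(n, i) * p ** i * (1 - p) ** (n - i) for i in range(k, n + 1))
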