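"""Independent brute-force oracles used to cross-check the statistics."""

from __future__ import annotations

import itertools
import math


def hypergeom_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = total = 0
    marked = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def nb_conditional_oracle(counts_test, counts_ref, phi: float) -> float:
    """Brute-force conditional NB test: enumerate every split of the total,
    computing the group-sum pmf directly from the gamma-function form."""
    n_a, n_b = len(counts_test), len(counts_ref)
    y_a = int(sum(counts_test))
    total = y_a + int(sum(counts_ref))
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)

    def log_pmf(y: int, n: int) -> float:
        mean = n * mu
        if phi == 0:
            return y * math.log(mean) - mean - math.lgamma(y + 1)
        r = n / phi
        p = r / (r + mean)
        return (
            math.lgamma(y + r) - math.lgamma(r) - math.lgamma(y + 1)
            + r * math.log(p) + y * math.log1p(-p)
        )

    probs = [
        math.exp(log_pmf(k, n_a) + log_pmf(total - k, n_b)) for k in range(total + 1)
    ]
    norm = sum(probs)
    obs = probs[y_a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-10)) / norm)
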