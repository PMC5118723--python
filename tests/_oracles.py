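"""Independent brute-force oracles shared by the test modules."""

import math


def brute_force_fisher(k1: int, n1: int, k2: int, n2: int) -> float:
    """Exact two-sided Fisher p via binomial-coefficient enumeration of every
    2x2 table with the observed margins (sums tables no more probable than
    the observed one, with a 1e-7 relative tie tolerance)."""
    K = k1 + k2
    weights = {
        x: math.comb(n1, x) * math.comb(n2, K - x)
        for x in range(max(0, K - n2), min(K, n1) + 1)
    }
    total = sum(weights.values())
    obs = weights[k1]
    kept = sum(w for w in weights.values() if w <= obs * (1 + 1e-7))
    return kept / total


def brute_force_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k) by direct summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def bh_step_up(p_values):
    """Hand-applied Benjamini-Hochberg step-up, aligned to input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q
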