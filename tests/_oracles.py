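"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (exact integer arithmetic, full
enumeration) and shares no code with the package implementation.
"""

from fractions import Fraction
from math import comb


def brute_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """P[X >= k] for X ~ Hypergeometric(N, K, n) by exact pmf summation."""
    total = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return Fraction(num, total)


def brute_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p: sum of all tables with pmf <= observed pmf."""
    N = a + b + c + d
    row = a + b
    col = a + c
    total = comb(N, col)

    def weight(x: int) -> int:
        return comb(row, x) * comb(N - row, col - x)

    obs = weight(a)
    lo, hi = max(0, col - (N - row)), min(row, col)
    num = sum(weight(x) for x in range(lo, hi + 1) if weight(x) <= obs)
    return Fraction(num, total)


def brute_neighbor_sort(corr_row: dict[str, float], focal: str,
                        n: int, r_min: float) -> list[tuple[str, float]]:
    """Full sort-and-slice of one correlation row (neighbor oracle)."""
    candidates = [
        (pid, r) for pid, r in corr_row.items()
        if pid != focal and r == r and r >= r_min
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return [(focal, 1.0)] + candidates[: n - 1]
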