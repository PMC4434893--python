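"""Exact hypergeometric over-representation testing.

The test statistic throughout the package is the inclusive upper tail

    P(X >= k)  with  X ~ Hypergeometric(N, K, n),

the standard convention for gene-set over-representation: the probability
of observing at least ``k`` known-positive entities when drawing ``n`` from
a universe of ``N`` containing ``K`` positives.  For moderate universes the
sum is evaluated in exact integer arithmetic (a single big-integer ratio),
so the result is correct to float rounding even at p ~ 1e-10 where naive
floating summation loses digits; very large universes fall back to scipy's
survival function.

The point probability P(X = k) is exposed alongside the tail because some
published enrichment figures turn out to be point masses rather than tails;
:func:`node_set_enrichment` reports both.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Collection

from scipy.stats import false_discovery_control, hypergeom

from .errors import ContractError

#: largest universe for which the exact integer-arithmetic sum is used
_EXACT_N_MAX = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and p-value of one upper-tail hypergeometric test."""

    N: int
    K: int
    n: int
    k: int
    p_value: float
    point_probability: float


def _check_args(N: int, K: int, n: int, k: int) -> None:
    for name, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(value, (int,)) or isinstance(value, bool):
            raise ContractError(f"{name} must be a non-negative integer, got {value!r}")
        if value < 0:
            raise ContractError(f"{name} must be >= 0, got {value}")
    if K > N:
        raise ContractError(f"K={K} exceeds universe size N={N}")
    if n > N:
        raise ContractError(f"n={n} exceeds universe size N={N}")
    if k > min(K, n):
        raise ContractError(f"k={k} exceeds min(K, n)={min(K, n)}")


def hypergeom_point(N: int, K: int, n: int, k: int) -> float:
    """Exact point probability P(X = k) for X ~ Hypergeometric(N, K, n)."""
    _check_args(N, K, n, k)
    if n - k > N - K:
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper-tail probability P(X >= k).

    Exact (big-integer) for N up to 10^4; scipy's survival function beyond.
    ``k = 0`` returns exactly 1.0.
    """
    _check_args(N, K, n, k)
    if k == 0:
        return 1.0
    if N <= _EXACT_N_MAX:
        numerator = sum(
            comb(K, j) * comb(N - K, n - j)
            for j in range(k, min(K, n) + 1)
            if n - j <= N - K
        )
        return numerator / comb(N, n)
    return float(hypergeom.sf(k - 1, N, K, n))


def node_set_enrichment(
    universe: Collection[str],
    known: Collection[str],
    selection: Collection[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``known`` within ``selection``.

    ``known`` is intersected with the universe before counting; the
    selection must be a subset of the universe.
    """
    universe = set(universe)
    known = set(known) & universe
    selection = set(selection)
    stray = selection - universe
    if stray:
        raise ContractError(
            "selection contains ids outside the universe: "
            + ", ".join(sorted(stray)[:10])
        )
    N, K, n = len(universe), len(known), len(selection)
    k = len(known & selection)
    return EnrichmentResult(
        N=N, K=K, n=n, k=k,
        p_value=hypergeom_upper_tail(N, K, n, k),
        point_probability=hypergeom_point(N, K, n, k),
    )


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (order preserved)."""
    if len(p_values) == 0:
        return []
    return list(false_discovery_control(p_values, method="bh"))
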