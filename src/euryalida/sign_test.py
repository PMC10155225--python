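"""Exact one-tailed sign test over sister-pair outcomes.

With each informative comparison treated as a fair coin under the null
hypothesis of trait-independent diversification, the test asks whether the
derived clade out-diversifies its sister more often than chance.  Ties
(equal richness) are dropped from *n*, the standard sign-test convention.
All tail probabilities are exact binomial sums in integer arithmetic —
*n* is tiny by construction, so no approximation is ever warranted.

Because the smallest attainable one-tailed p-value is 2^-n, a unanimous
sample cannot reach significance below a minimum number of comparisons
(:func:`min_comparisons`); a result with fewer informative pairs is
reported as not applicable rather than non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable

from .sister import SisterPair

__all__ = ["SignTestResult", "binom_upper_tail", "min_comparisons", "sign_test"]


@dataclass(frozen=True)
class SignTestResult:
    """Outcome of the exact sign test on a set of sister pairs."""

    n_pairs: int
    n_ties: int
    n_informative: int
    k_plus: int
    p_value: float
    p_exact: Fraction
    alpha: float
    min_n_required: int
    applicable: bool
    significant: bool

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_ties": self.n_ties,
            "n_informative": self.n_informative,
            "k_plus": self.k_plus,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "min_n_required": self.min_n_required,
            "applicable": self.applicable,
            "significant": self.significant,
        }


def binom_upper_tail(k: int, n: int) -> Fraction:
    """Exact P(X >= k) for X ~ Binomial(n, 1/2), as a reduced fraction."""
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2 ** n)


def min_comparisons(alpha: float) -> int:
    """Smallest n at which a unanimous outcome can be significant.

    That is, the least n with P(X >= n) = 2^-n <= alpha.  At the
    conventional alpha = 0.05 this is 5 comparisons.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    alpha_exact = Fraction(alpha)
    n = 1
    while Fraction(1, 2 ** n) > alpha_exact:
        n += 1
    return n


def sign_test(pairs: Iterable[SisterPair], alpha: float = 0.05,
              two_tailed: bool = False) -> SignTestResult:
    """Exact sign test of "derived clade more speciose" over sister pairs.

    Ties are excluded from *n*; the one-tailed p-value is the exact upper
    binomial tail at the observed number of ``plus`` outcomes.  When fewer
    informative pairs are available than :func:`min_comparisons` requires,
    ``applicable`` is False and ``significant`` is forced False whatever
    the tail probability.  A two-tailed variant is available behind the
    ``two_tailed`` flag but the directional test is the default: the
    hypothesis under scrutiny is that the innovation *raises* diversity.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("sign test needs at least one sister pair")
    n_pairs = len(pairs)
    n_ties = sum(1 for p in pairs if p.outcome == "zero")
    n = n_pairs - n_ties
    k_plus = sum(1 for p in pairs if p.outcome == "plus")
    if n == 0:
        p_exact = Fraction(1)
    elif two_tailed:
        upper = binom_upper_tail(k_plus, n)
        lower = Fraction(sum(comb(n, i) for i in range(0, k_plus + 1)), 2 ** n)
        p_exact = min(Fraction(1), 2 * min(upper, lower))
    else:
        p_exact = binom_upper_tail(k_plus, n)
    min_n = min_comparisons(alpha)
    applicable = n >= min_n
    return SignTestResult(
        n_pairs=n_pairs,
        n_ties=n_ties,
        n_informative=n,
        k_plus=k_plus,
        p_value=float(p_exact),
        p_exact=p_exact,
        alpha=alpha,
        min_n_required=min_n,
        applicable=applicable,
        significant=bool(applicable and p_exact <= Fraction(alpha)),
    )
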