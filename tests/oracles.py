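"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the loss-model
profile probabilities are computed by exact combinatorics (sequential
uniform chromatid loss is equivalent to drawing a uniform random subset of
the 92 chromatids, conditioned on viability), and the small-step cases are
additionally enumerated step by step over ordered loss sequences.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb, factorial


def viable_loss_subsets(n_lost: int, max_lost_per_type: int = 3, n_types: int = 23,
                        start_copies: int = 4) -> int:
    """Number of ways to lose ``n_lost`` distinguishable chromatids with at
    most ``max_lost_per_type`` removed from any chromosome type: the x^L
    coefficient of (sum_k C(c, k) x^k)^n_types."""
    poly = [1]
    base = [comb(start_copies, k) for k in range(max_lost_per_type + 1)]
    for _ in range(n_types):
        new = [0] * (len(poly) + len(base) - 1)
        for i, a in enumerate(poly):
            for j, b in enumerate(base):
                new[i + j] += a * b
        poly = new
    return poly[n_lost] if n_lost < len(poly) else 0


def loss_profile_probability(
    class_counts: dict[int, int],
    monosomy_selection: bool = False,
    n_types: int = 23,
    start_copies: int = 4,
) -> Fraction:
    """Exact probability of a copy-number class profile under loss from
    tetraploidy with nullisomy (and optionally monosomy) elimination."""
    if sum(class_counts.values()) != n_types:
        raise ValueError("class counts must cover every chromosome type")
    n_lost = sum((start_copies - k) * v for k, v in class_counts.items())
    ways = factorial(n_types)
    for k, v in class_counts.items():
        ways //= factorial(v)
        ways *= comb(start_copies, start_copies - k) ** v
    max_lost = start_copies - 2 if monosomy_selection else start_copies - 1
    if any(k < start_copies - max_lost for k in class_counts):
        return Fraction(0)
    return Fraction(ways, viable_loss_subsets(n_lost, max_lost, n_types, start_copies))


def enumerate_loss_distribution(
    n_steps: int, n_types: int = 23, start_copies: int = 4
) -> dict[tuple[int, ...], Fraction]:
    """Step-by-step enumeration of the loss process for small step counts.

    Walks every ordered sequence of type-level losses with its exact
    probability (proportional to current copy number at each step), drops
    sequences creating a nullisomy, renormalises over the survivors, and
    returns probabilities keyed by sorted copy-number vectors.
    """
    dist: dict[tuple[int, ...], Fraction] = {}

    def recurse(copies: tuple[int, ...], prob: Fraction, steps_left: int):
        if steps_left == 0:
            if min(copies) > 0:
                key = tuple(sorted(copies))
                dist[key] = dist.get(key, Fraction(0)) + prob
            return
        total = sum(copies)
        # group identical copy counts: picking any of the v types with c
        # copies yields the same sorted outcome
        for c, v in Counter(copies).items():
            if c == 0:
                continue
            i = copies.index(c)
            child = copies[:i] + (c - 1,) + copies[i + 1 :]
            recurse(child, prob * Fraction(c * v, total), steps_left - 1)

    recurse((start_copies,) * n_types, Fraction(1), n_steps)
    total = sum(dist.values())
    return {k: v / total for k, v in dist.items()}


def pearson_chisq(observed, expected) -> float:
    """Textbook Pearson statistic: sum (O - E)^2 / E."""
    return float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
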