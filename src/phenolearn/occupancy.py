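"""Capacity-constrained occupancy combinatorics.

A screen over a duplicated experiment grid groups logically equivalent
experiments into *quads* of four.  After a campaign one asks: given that ``z``
experiments were performed over ``b`` quads (each quad holding at most
``capacity`` experiments), how surprising is it that ``f`` distinct quads were
touched?  The null model treats every capacity-respecting way of distributing
``z`` indistinguishable balls over ``b`` distinguishable bins as equiprobable,
so that

    P(f) = C(b, f) * [x^z](x + x^2 + ... + x^c)^f  /  [x^z](1 + x + ... + x^c)^b

where ``[x^z]`` extracts the coefficient of ``x^z`` and ``c`` is the per-bin
capacity.  The numerator counts the ways of choosing which ``f`` bins are hit
and then filling each with at least one ball; the denominator counts all
capacity-respecting distributions.

Two numeric modes are provided: an exact big-integer/rational mode (reference,
small to moderate ``z``) and a log-space dynamic program (default; all terms
are nonnegative so there is no cancellation) that handles campaign-scale
instances such as z=2697 balls over b=2304 quads in seconds.

Also included is the closed-form minimum number of experiments needed for a
perfect model of an ``n x n`` latent space that was secretly duplicated to
``2n x 2n``: observing the ``n x n`` block plus the two off-diagonal bands
costs ``n^2 + 2n`` of the ``4n^2`` experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil, comb, inf

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "count_fillings",
    "occupancy_pmf",
    "nonrandomness_tail_p",
    "ideal_minimum",
    "OccupancyPMF",
]


def count_fillings(z: int, f: int, capacity: int = 4) -> int:
    """Number of ways to write ``z`` as an ordered sum of ``f`` parts in 1..capacity.

    This is the coefficient ``[x^z](x + x^2 + ... + x^capacity)^f``, computed
    exactly with big integers via the recurrence
    ``N(z, f) = sum_{k=1..capacity} N(z - k, f - 1)`` with ``N(0, 0) = 1``.
    Out-of-range arguments count zero ways.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    if z < 0 or f < 0:
        return 0
    if f == 0:
        return 1 if z == 0 else 0
    if z < f or z > f * capacity:
        return 0
    prev = [0] * (z + 1)
    prev[0] = 1
    for part in range(1, f + 1):
        cur = [0] * (z + 1)
        lo, hi = part, min(z, part * capacity)
        for total in range(lo, hi + 1):
            s = 0
            for k in range(1, capacity + 1):
                if total - k >= 0:
                    s += prev[total - k]
            cur[total] = s
        prev = cur
    return prev[z]


def _log_fillings_row(z: int, f_max: int, capacity: int) -> np.ndarray:
    """log N(z, f) for f = 0..f_max via a vectorized DP over parts.

    Returns an array of shape (f_max + 1,) of natural logs (-inf for zero).
    """
    # work[t] = log N(t, f) for the current f, t = 0..z
    work = np.full(z + 1, -inf)
    work[0] = 0.0
    out = np.full(f_max + 1, -inf)
    out[0] = work[z]
    shifted = np.empty((capacity, z + 1))
    for f in range(1, f_max + 1):
        for k in range(1, capacity + 1):
            shifted[k - 1, :] = -inf
            if k <= z:
                shifted[k - 1, k:] = work[: z + 1 - k]
        work = logsumexp(shifted, axis=0)
        out[f] = work[z]
        if f * capacity >= z and work[z] == -inf and f > z:
            break  # all remaining rows are -inf as well once f > z
    return out


@dataclass(frozen=True)
class OccupancyPMF:
    """Distribution of the number of occupied bins ``f``.

    Attributes
    ----------
    f_values : integer array of the support (ceil(z/capacity) .. min(z, b))
    probs : probabilities aligned with ``f_values`` (float)
    z, b, capacity : problem parameters
    method : "log" or "exact"
    """

    f_values: np.ndarray
    probs: np.ndarray
    z: int
    b: int
    capacity: int
    method: str

    def tail(self, f_observed: int) -> float:
        """P(f >= f_observed)."""
        mask = self.f_values >= f_observed
        return float(self.probs[mask].sum())


def _support(z: int, b: int, capacity: int) -> range:
    if z == 0:
        return range(0, 1)
    return range(ceil(z / capacity), min(z, b) + 1)


def occupancy_pmf(z: int, b: int, capacity: int = 4, method: str = "log") -> OccupancyPMF:
    """PMF of the number of bins hit when z balls land in b capacity-limited bins.

    Parameters
    ----------
    z : number of balls (experiments performed)
    b : number of bins (quads)
    capacity : maximum balls per bin (4 for a duplicated-pair screen)
    method : "log" (log-space DP, default) or "exact" (big-integer rationals)
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if z < 0:
        raise ValueError("z must be >= 0")
    if z > capacity * b:
        raise ValueError(f"infeasible: z={z} exceeds capacity*b={capacity * b}")
    support = _support(z, b, capacity)
    fs = np.array(list(support), dtype=int)
    if method == "exact":
        weights = [comb(b, int(f)) * count_fillings(z, int(f), capacity) for f in fs]
        total = sum(weights)
        probs = np.array([float(Fraction(w, total)) for w in weights])
    elif method == "log":
        log_n = _log_fillings_row(z, fs[-1], capacity)[fs]
        log_binom = (
            gammaln(b + 1) - gammaln(fs + 1.0) - gammaln(b - fs + 1.0)
        )
        logw = log_binom + log_n
        probs = np.exp(logw - logsumexp(logw))
    else:
        raise ValueError(f"unknown method {method!r}")
    return OccupancyPMF(f_values=fs, probs=probs, z=z, b=b, capacity=capacity, method=method)


def nonrandomness_tail_p(
    z: int, b: int, f_observed: int, capacity: int = 4, method: str = "log"
) -> float:
    """Upper-tail probability P(f >= f_observed) under the occupancy null.

    A small value means a random process would rarely have spread its ``z``
    experiments over at least ``f_observed`` distinct quads, i.e. the observed
    sampling pattern is non-random in the direction of high coverage.
    """
    if method == "exact":
        support = _support(z, b, capacity)
        weights = {f: comb(b, f) * count_fillings(z, f, capacity) for f in support}
        total = sum(weights.values())
        tail = sum(w for f, w in weights.items() if f >= f_observed)
        return float(Fraction(tail, total))
    return occupancy_pmf(z, b, capacity, method=method).tail(f_observed)


def ideal_minimum(n: int) -> tuple[int, float]:
    """Fewest experiments needed for a perfect model of a duplicated n x n space.

    With ``n`` latent targets and ``n`` latent conditions each duplicated into
    two visible ids, observing the leading ``n x n`` block reveals every
    phenotype, and the two length-``n`` diagonals through the duplicate bands
    identify which duplicate ids correspond — ``n^2 + 2n`` experiments out of
    ``4n^2`` total.

    Returns ``(count, fraction_of_total)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    count = n * n + 2 * n
    return count, count / (4 * n * n)
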