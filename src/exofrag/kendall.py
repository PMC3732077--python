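"""Kendall rank correlation (tau-b) with tie correction.

The statistic is computed from concordant/discordant pair counts with the
usual tie corrections in both margins.  Two-sided p-values come from exact
enumeration of all permutations of one margin for n <= 8 (valid with ties),
and from the normal approximation with tie-adjusted variance of S otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedResultError

EXACT_MAX_N = 8
_CHUNK = 1024


@dataclass(frozen=True)
class CorrelationResult:
    """A rank-correlation estimate: tau-b, two-sided p, sample size, stratum label."""

    tau: float
    p_value: float
    n: int
    stratum: str = ""


def _s_statistic(x: np.ndarray, y: np.ndarray) -> int:
    """Sum over unordered pairs of sign(xi - xj) * sign(yi - yj)."""
    n = len(x)
    total = 0
    for i0 in range(0, n, _CHUNK):
        xs = np.sign(x[i0 : i0 + _CHUNK, None] - x[None, :])
        ys = np.sign(y[i0 : i0 + _CHUNK, None] - y[None, :])
        total += int(np.sum(xs * ys))
    return total // 2  # ordered pairs count each unordered pair twice


def _tie_sizes(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _exact_p(x: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    """P(|S| >= |S_obs|) over all permutations of y against fixed x.

    The tau-b denominator depends only on the tie structure of each margin,
    which permutation preserves, so comparing S is comparing |tau|.
    """
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    yp = y[perms]  # (n!, n)
    s = np.zeros(len(perms), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        sx = np.sign(x[i] - x[j])
        if sx:
            s += (sx * np.sign(yp[:, i] - yp[:, j])).astype(np.int64)
    return float(np.mean(np.abs(s) >= abs(s_obs)))


def _asymptotic_p(x: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    """Normal approximation with the tie-adjusted variance of S."""
    n = len(x)
    tx = _tie_sizes(x).astype(float)
    ty = _tie_sizes(y).astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    var_s = (v0 - vt - vu) / 18.0
    var_s += (
        float(np.sum(tx * (tx - 1) * (tx - 2)))
        * float(np.sum(ty * (ty - 1) * (ty - 2)))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var_s += (
        float(np.sum(tx * (tx - 1))) * float(np.sum(ty * (ty - 1))) / (2.0 * n * (n - 1))
    )
    if var_s <= 0:
        return 1.0
    z = s_obs / math.sqrt(var_s)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def kendall_tau_b(
    x, y, stratum: str = "", exact_max_n: int = EXACT_MAX_N
) -> CorrelationResult:
    """Kendall tau-b between x and y with a two-sided p-value.

    Parameters
    ----------
    x, y
        Equal-length numeric sequences, n >= 3.  Ties in either margin are
        handled by the tau-b correction.
    stratum
        Free-text label carried into the result (e.g. ``"UTR, ECER>=10"``).
    exact_max_n
        Largest n for which the p-value is computed by full permutation
        enumeration rather than the normal approximation.

    Raises
    ------
    InsufficientDataError
        If n < 3 or the lengths differ.
    UndefinedResultError
        If either margin is fully tied (tau-b undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError(
            f"x and y must be equal-length 1-d sequences, got {x.shape} and {y.shape}"
        )
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"Kendall tau requires n >= 3, got n = {n}")

    n0 = n * (n - 1) // 2
    tx = _tie_sizes(x)
    ty = _tie_sizes(y)
    denom_x = n0 - int(np.sum(tx * (tx - 1) // 2))
    denom_y = n0 - int(np.sum(ty * (ty - 1) // 2))
    if denom_x == 0 or denom_y == 0:
        which = "x" if denom_x == 0 else "y"
        raise UndefinedResultError(f"tau-b undefined: all values of {which} are tied")

    s = _s_statistic(x, y)
    tau = s / math.sqrt(denom_x * denom_y)
    if n <= exact_max_n:
        p = _exact_p(x, y, s)
    else:
        p = _asymptotic_p(x, y, s)
    p = float(min(1.0, max(p, np.nextafter(0.0, 1.0))))
    return CorrelationResult(tau=float(tau), p_value=p, n=n, stratum=stratum)
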