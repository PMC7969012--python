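"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, exhaustive
enumeration, direct numerical integration) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def brute_force_curve(fragments, mode: str, x_max: int, estimator: str):
    """Curve values by an all-pairs (i, j) double loop over each fragment.

    For every unsigned lag x, every ordered pair (i, j) with |i - j| = x
    is visited; the auto mode de-duplicates the symmetric pair by
    requiring i <= j.  Returns an array of length x_max + 1 with NaN at
    lags no fragment contributes to.
    """
    per_lag_fragment_means = [[] for _ in range(x_max + 1)]
    per_lag_pooled = [[] for _ in range(x_max + 1)]
    for frag in fragments:
        s, r = frag.s, frag.r
        L = len(s)
        sums = np.zeros(x_max + 1)
        counts = np.zeros(x_max + 1, dtype=int)
        for i in range(L):
            for j in range(L):
                x = abs(i - j)
                if x > x_max:
                    continue
                if mode == "auto":
                    if i > j:
                        continue
                    prod = s[i] * s[j]
                else:
                    prod = s[i] * r[j]
                sums[x] += prod
                counts[x] += 1
                per_lag_pooled[x].append(prod)
        for x in range(x_max + 1):
            if counts[x]:
                per_lag_fragment_means[x].append(sums[x] / counts[x])
    values = np.full(x_max + 1, np.nan)
    for x in range(x_max + 1):
        if estimator == "fragment_mean":
            if per_lag_fragment_means[x]:
                values[x] = float(np.mean(per_lag_fragment_means[x]))
        else:
            if per_lag_pooled[x]:
                values[x] = float(np.mean(per_lag_pooled[x]))
    return values


def t_pvalue_by_integration(sample) -> float:
    """Two-sided one-sample t p-value via direct integration of the t density."""
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    df = n - 1
    t = sample.mean() / (sample.std(ddof=1) / math.sqrt(n))
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(u):
        return const * (1.0 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t), np.inf)
    return 2.0 * tail


def mann_whitney_exact_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Returns ``(U_a, p)`` where ``U_a`` counts pairs with a > b (halves
    for ties) and p uses the two-sided doubling rule
    ``min(1, 2 * min(P(U <= u), P(U >= u)))`` on the permutation null.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def g_statistic_closed_form(counts) -> tuple[float, float]:
    """G = 2 sum O ln(O/E) and its chi-square(1) p via erfc.

    chi-square with one degree of freedom is the square of a standard
    normal, so P(X > g) = erfc(sqrt(g / 2)).
    """
    o = np.asarray(counts, dtype=float)
    row = o.sum(axis=1, keepdims=True)
    col = o.sum(axis=0, keepdims=True)
    e = row * col / o.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    g = 2.0 * terms.sum()
    return float(g), float(math.erfc(math.sqrt(max(g, 0.0) / 2.0)))
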