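"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, textbook formulas) without touching the package's own
implementations, so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_episodes(
    values: np.ndarray, threshold: float, interval_min: float
) -> list[tuple[int, int, float]]:
    """Enumerate qualifying hypoglycaemia episodes by explicit scanning.

    Returns (first_below_index, last_below_index_exclusive, duration_min)
    per episode.  A run of samples <= threshold joins the previous run if
    the above-threshold gap between them is <= 20 min; an episode
    qualifies when its summed below time (below samples x interval) is
    >= 20 min.
    """
    below = [bool(v <= threshold) for v in values]
    runs = []
    i = 0
    n = len(values)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    clusters: list[list[tuple[int, int]]] = []
    for run in runs:
        if clusters and (run[0] - clusters[-1][-1][1]) * interval_min <= 20.0:
            clusters[-1].append(run)
        else:
            clusters.append([run])
    episodes = []
    for cluster in clusters:
        below_samples = sum(b - a for a, b in cluster)
        duration = below_samples * interval_min
        if duration >= 20.0:
            episodes.append((cluster[0][0], cluster[-1][1], duration))
    return episodes


def brute_force_mage(values: np.ndarray) -> float | None:
    """MAGE by explicit extrema classification on the deduplicated series.

    Each plateau-collapsed point is classified as peak or trough against
    its neighbours; swings between consecutive extrema that exceed one SD
    (n-1) of the full series qualify; the mean of qualifying swings taken
    in the direction of the first qualifying swing is returned.
    """
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1))
    dedup_idx = [0]
    for i in range(1, len(values)):
        if values[i] != values[dedup_idx[-1]]:
            dedup_idx.append(i)
    pts = [values[i] for i in dedup_idx]
    if len(pts) < 2:
        return None
    extrema = [pts[0]]
    for k in range(1, len(pts) - 1):
        if (pts[k] > pts[k - 1] and pts[k] > pts[k + 1]) or (
            pts[k] < pts[k - 1] and pts[k] < pts[k + 1]
        ):
            extrema.append(pts[k])
    extrema.append(pts[-1])
    swings = [b - a for a, b in zip(extrema[:-1], extrema[1:])]
    qualifying = [s for s in swings if abs(s) > sd]
    if not qualifying:
        return None
    direction = 1.0 if qualifying[0] > 0 else -1.0
    kept = [abs(s) for s in qualifying if (s > 0) == (direction > 0)]
    return float(np.mean(kept))


def chi2_2x2_by_hand(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square for a 2x2 table via n(ad - bc)^2 / product of
    margins."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def paired_t_by_hand(diffs) -> tuple[float, int]:
    """t statistic and df from the textbook formula."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return float(t), n - 1


def poisson_ci_by_tail_inversion(k: int, alpha: float = 0.05,
                                 tol: float = 1e-10) -> tuple[float, float]:
    """Exact Poisson CI for a count k by bisecting on summed tail
    probabilities (no chi-square quantiles involved)."""
    from math import exp, lgamma, log

    def pmf_sum_upper(lam: float, kk: int) -> float:
        # P(X >= kk) for X ~ Poisson(lam)
        s = 0.0
        for i in range(0, kk):
            s += exp(i * log(lam) - lam - lgamma(i + 1))
        return 1.0 - s

    def pmf_sum_lower(lam: float, kk: int) -> float:
        # P(X <= kk)
        s = 0.0
        for i in range(0, kk + 1):
            s += exp(i * log(lam) - lam - lgamma(i + 1))
        return s

    if k == 0:
        lower = 0.0
    else:
        lo, hi = 1e-12, k + 1.0
        while pmf_sum_upper(hi, k) < alpha / 2:
            hi *= 2
        for _ in range(200):
            mid = (lo + hi) / 2
            if pmf_sum_upper(mid, k) < alpha / 2:
                lo = mid
            else:
                hi = mid
        lower = (lo + hi) / 2
    lo, hi = float(k), float(k) + 1.0
    while pmf_sum_lower(hi, k) > alpha / 2:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if pmf_sum_lower(mid, k) > alpha / 2:
            lo = mid
        else:
            hi = mid
    upper = (lo + hi) / 2
    return lower, upper
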