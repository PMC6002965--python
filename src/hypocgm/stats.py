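"""Group-comparison statistics for the low-vs-high C-peptide contrasts.

Paired t tests for matched continuous outcomes, Pearson chi-square (no
continuity correction by default) for proportions, exact Garwood
(chi-square quantile) CIs for Poisson rates, a log-scale z test for rate
ratios, and adjusted logistic / Poisson / linear (ANCOVA) models fitted
by maximum likelihood via statsmodels.  Two-sided tests throughout.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InputError, NonConvergenceError
from .types import GroupComparison

DEFAULT_CONTRAST = "low vs high C-peptide"


def paired_t(
    differences: Sequence[float],
    outcome: str = "",
    contrast: str = DEFAULT_CONTRAST,
) -> GroupComparison:
    """Classic paired t test on within-pair differences (df = n-1)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InputError("paired t needs at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateInputError("paired differences have zero variance")
    n = d.size
    mean = float(np.mean(d))
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2 * sps.t.sf(abs(t), df=n - 1))
    tcrit = float(sps.t.ppf(0.975, df=n - 1))
    return GroupComparison(
        outcome=outcome,
        contrast=contrast,
        effect_type="mean difference",
        estimate=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        p_value=p,
        method="paired t",
    )


def chi_square_2x2(
    a: int,
    b: int,
    c: int,
    d: int,
    outcome: str = "",
    contrast: str = DEFAULT_CONTRAST,
    continuity_correction: bool = False,
) -> GroupComparison:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    Rows are groups, columns outcome yes/no.  The reported estimate is
    the difference in proportions a/(a+b) - c/(c+d).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or not np.all(table == np.floor(table)):
        raise InputError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateInputError("chi-square table has an empty margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=continuity_correction)
    p1, p2 = a / (a + b), c / (c + d)
    diff = p1 - p2
    # Wald CI for the difference in proportions
    se = math.sqrt(p1 * (1 - p1) / (a + b) + p2 * (1 - p2) / (c + d))
    return GroupComparison(
        outcome=outcome,
        contrast=contrast,
        effect_type="proportion difference",
        estimate=diff,
        ci_low=diff - 1.96 * se,
        ci_high=diff + 1.96 * se,
        p_value=float(p),
        method="chi-square"
        + (" (continuity corrected)" if continuity_correction else ""),
        flags=(f"chi2={float(chi2):.6g}",),
    )


def poisson_rate_ci(
    events: int, exposure: float, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Rate with exact (Garwood) CI from chi-square quantiles.

    Returns (rate, lower, upper); the lower bound is 0 when events = 0.
    """
    if events < 0 or events != int(events):
        raise InputError("event count must be a non-negative integer")
    if exposure <= 0:
        raise InputError("exposure must be positive")
    k = int(events)
    lower = 0.0 if k == 0 else float(sps.chi2.ppf(alpha / 2, 2 * k) / 2)
    upper = float(sps.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2)
    return k / exposure, lower / exposure, upper / exposure


def rate_compare(
    events1: int,
    exposure1: float,
    events2: int,
    exposure2: float,
    outcome: str = "",
    contrast: str = DEFAULT_CONTRAST,
) -> GroupComparison:
    """Rate ratio with log-scale Wald CI and z test on the event counts."""
    if exposure1 <= 0 or exposure2 <= 0:
        raise InputError("exposures must be positive")
    for k in (events1, events2):
        if k < 0 or k != int(k):
            raise InputError("event counts must be non-negative integers")
    r1, r2 = events1 / exposure1, events2 / exposure2
    if events1 == 0 or events2 == 0:
        ratio = math.inf if (r2 == 0 and r1 > 0) else (r1 / r2 if r2 > 0 else math.nan)
        return GroupComparison(
            outcome=outcome,
            contrast=contrast,
            effect_type="rate ratio",
            estimate=ratio,
            ci_low=0.0,
            ci_high=math.inf,
            p_value=None,
            method="rate ratio z test",
            flags=("unbounded CI: zero events in a group",),
        )
    se = math.sqrt(1.0 / events1 + 1.0 / events2)
    log_rr = math.log(r1 / r2)
    z = log_rr / se
    p = float(2 * sps.norm.sf(abs(z)))
    return GroupComparison(
        outcome=outcome,
        contrast=contrast,
        effect_type="rate ratio",
        estimate=r1 / r2,
        ci_low=math.exp(log_rr - 1.96 * se),
        ci_high=math.exp(log_rr + 1.96 * se),
        p_value=p,
        method="rate ratio z test",
        flags=(f"z={z:.6g}",),
    )


def adjusted_models(
    data: pd.DataFrame,
    outcome: str,
    kind: str,
    group_col: str = "group_low",
    covariates: Sequence[str] = (),
    exposure_col: Optional[str] = None,
    contrast: str = DEFAULT_CONTRAST,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GroupComparison:
    """Adjusted group effect from a converged maximum-likelihood fit.

    kind = "binary" (logistic, OR), "count" (Poisson log-link with
    exposure offset, rate ratio) or "continuous" (linear / ANCOVA,
    adjusted mean difference).  ``group_col`` must be a 0/1 indicator of
    the low-C-peptide group.  Separation or non-convergence raises
    :class:`NonConvergenceError` rather than returning silently.
    """
    import statsmodels.api as sm

    if kind not in ("binary", "count", "continuous"):
        raise InputError(f"unknown outcome kind {kind!r}")
    cols = [outcome, group_col, *covariates]
    if exposure_col:
        cols.append(exposure_col)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise InputError(f"missing columns: {missing}")
    df = data[cols].dropna()
    X = sm.add_constant(df[[group_col, *covariates]].astype(float))
    y = df[outcome].astype(float)

    try:
        if kind == "binary":
            model = sm.GLM(y, X, family=sm.families.Binomial())
        elif kind == "count":
            offset = (
                np.log(df[exposure_col].astype(float)) if exposure_col else None
            )
            model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        else:
            model = sm.OLS(y, X)
        res = model.fit(maxiter=max_iter, tol=tol) if kind != "continuous" else model.fit()
    except Exception as exc:  # perfect separation, singular design, ...
        raise NonConvergenceError(f"model fit failed: {exc}") from exc
    if kind != "continuous" and not getattr(res, "converged", True):
        raise NonConvergenceError(
            f"IRLS did not converge within {max_iter} iterations"
        )

    coef = float(res.params[group_col])
    se = float(res.bse[group_col])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 1e3:
        raise NonConvergenceError("unstable group coefficient (separation?)")
    p = float(res.pvalues[group_col])
    lo, hi = coef - 1.96 * se, coef + 1.96 * se
    if kind == "binary":
        eff, est, ci = "odds ratio", math.exp(coef), (math.exp(lo), math.exp(hi))
    elif kind == "count":
        eff, est, ci = "rate ratio", math.exp(coef), (math.exp(lo), math.exp(hi))
    else:
        eff, est, ci = "mean difference", coef, (lo, hi)
    label = {"binary": "logistic", "count": "Poisson", "continuous": "ANCOVA"}[kind]
    return GroupComparison(
        outcome=outcome,
        contrast=contrast,
        effect_type=eff,
        estimate=est,
        ci_low=ci[0],
        ci_high=ci[1],
        p_value=p,
        adjusted_for=tuple(covariates),
        method=f"{label} regression",
    )
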