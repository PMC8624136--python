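"""Pearson correlation screening of spectral indices against yield traits.

Correlations are computed on genotype means within a scope (one year,
or across years) and flagged significant when |r| meets the two-tailed
critical value at alpha = 0.05 for the available n — for n = 64 that
threshold is 0.25 (2 d.p.).  Strength categories follow fixed bins:
below the critical value "ns", then weak (< 0.50), moderate (< 0.70)
and strong (>= 0.70), sign-blind, boundaries assigned upward.

No multiple-testing correction is applied by default (the screening
convention this implements uses none); Holm adjustment is available
behind an off-by-default flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

STRENGTH_NS = "ns"
STRENGTH_WEAK = "weak"
STRENGTH_MODERATE = "moderate"
STRENGTH_STRONG = "strong"


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |r| for a Pearson correlation on n pairs.

    ``r* = t* / sqrt(t*^2 + n - 2)`` with ``t*`` the (1 - alpha/2)
    quantile of Student's t on n - 2 degrees of freedom.  Strictly
    decreasing in n; 0.25 (2 d.p.) at n = 64, alpha = 0.05.
    """
    if n < 3:
        raise ValueError("critical r requires n >= 3")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_star / np.sqrt(t_star**2 + n - 2))


def strength_category(r: float, n: int, alpha: float = 0.05) -> str:
    """Correlation strength bin (sign-blind)."""
    if abs(r) > 1 + 1e-12:
        raise ValueError("|r| cannot exceed 1")
    a = abs(r)
    if a < critical_r(n, alpha):
        return STRENGTH_NS
    if a < 0.50:
        return STRENGTH_WEAK
    if a < 0.70:
        return STRENGTH_MODERATE
    return STRENGTH_STRONG


def correlation_table(
    sri: pd.DataFrame,
    targets: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Long-format correlation screen of every SRI against every target.

    Both inputs are genotype-indexed DataFrames; rows are aligned on the
    shared genotypes.  Output columns: ``sri, target, r, n, significant,
    strength``.  A constant column gives an undefined (NaN) cell flagged
    non-significant, never a silent zero.
    """
    common = sri.index.intersection(targets.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared genotypes")
    X = sri.loc[common]
    Y = targets.loc[common]
    n = len(common)
    rows = []
    for sname in X.columns:
        x = X[sname].to_numpy(float)
        for tname in Y.columns:
            y = Y[tname].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            m = int(ok.sum())
            if m < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((sname, tname, np.nan, m, False, STRENGTH_NS, np.nan))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                (sname, tname, float(r), m, None, strength_category(r, m, alpha), p)
            )
    out = pd.DataFrame(
        rows, columns=["sri", "target", "r", "n", "significant", "strength", "p"]
    )
    defined = out["r"].notna()
    if holm:
        out.loc[defined, "significant"] = _holm(out.loc[defined, "p"].to_numpy(), alpha)
    else:
        crit = out.loc[defined, "n"].map(lambda m: critical_r(int(m), alpha))
        out.loc[defined, "significant"] = out.loc[defined, "r"].abs() >= crit
    out["significant"] = out["significant"].astype(bool)
    return out.drop(columns="p")


def _holm(pvals: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
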