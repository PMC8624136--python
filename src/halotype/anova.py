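"""Per-year fixed-effects split-plot ANOVA.

Field layout: a randomized complete block design with a split-plot
arrangement — salinity treatment (ST) in main plots within each block
(replicate), genotype (G) in subplots.  The classical decomposition for
r blocks x a main-plot levels x b subplot levels (one observation per
cell) is

====================  ==================
source                degrees of freedom
====================  ==================
Rep                   r - 1
ST                    a - 1
Error(a) = Rep x ST   (r - 1)(a - 1)
G                     b - 1
ST x G                (a - 1)(b - 1)
Error(b)              a(r - 1)(b - 1)
Total                 rab - 1
====================  ==================

ST is tested against Error(a); G and ST x G against Error(b).  For the
study layout (r=3, a=2, b=64) the d.f. are 2/1/2/63/63/252, total 383.
Only balanced layouts are supported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regression import significance_code


def splitplot_anova(
    data: pd.DataFrame,
    response: str,
    rep_col: str = "rep",
    main_col: str = "treatment",
    sub_col: str = "genotype",
) -> pd.DataFrame:
    """Split-plot ANOVA table for one response.

    Returns a DataFrame indexed by source with columns
    ``df, ss, ms, F, p, sig``; F and p are blank for error terms and
    the total row.

    Raises
    ------
    ValueError
        If the layout is unbalanced (any cell count differs from one).
    """
    for col in (rep_col, main_col, sub_col, response):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    counts = data.groupby([rep_col, main_col, sub_col], observed=True).size()
    r = data[rep_col].nunique()
    a = data[main_col].nunique()
    b = data[sub_col].nunique()
    if len(counts) != r * a * b or (counts != 1).any():
        raise ValueError(
            "unbalanced layout: expected exactly one observation per "
            "rep x main-plot x subplot cell"
        )

    y = data[response].to_numpy(float)
    grand = y.mean()
    N = len(y)

    def ss_means(by, weight):
        means = data.groupby(by, observed=True)[response].mean()
        return weight * float(((means - grand) ** 2).sum()), means

    ss_total = float(((y - grand) ** 2).sum())
    ss_rep, m_rep = ss_means(rep_col, a * b)
    ss_main, m_main = ss_means(main_col, r * b)
    ss_sub, m_sub = ss_means(sub_col, r * a)

    # whole-plot error: Rep x ST interaction of main-plot means
    m_ra = data.groupby([rep_col, main_col], observed=True)[response].mean()
    dev_ra = (
        m_ra
        - m_rep.reindex(m_ra.index.get_level_values(0)).to_numpy()
        - m_main.reindex(m_ra.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_err_a = b * float((dev_ra**2).sum())

    m_ab = data.groupby([main_col, sub_col], observed=True)[response].mean()
    dev_ab = (
        m_ab
        - m_main.reindex(m_ab.index.get_level_values(0)).to_numpy()
        - m_sub.reindex(m_ab.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_inter = r * float((dev_ab**2).sum())

    ss_err_b = ss_total - (ss_rep + ss_main + ss_err_a + ss_sub + ss_inter)
    ss_err_b = max(ss_err_b, 0.0)

    df = {
        "Rep": r - 1,
        "ST": a - 1,
        "Error_a": (r - 1) * (a - 1),
        "G": b - 1,
        "ST x G": (a - 1) * (b - 1),
        "Error_b": a * (r - 1) * (b - 1),
        "Total": N - 1,
    }
    ss = {
        "Rep": ss_rep,
        "ST": ss_main,
        "Error_a": ss_err_a,
        "G": ss_sub,
        "ST x G": ss_inter,
        "Error_b": ss_err_b,
        "Total": ss_total,
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in df}

    def ftest(effect, error):
        if ms[error] == 0 or df[error] == 0:
            return np.nan, np.nan
        f = ms[effect] / ms[error]
        return f, float(stats.f.sf(f, df[effect], df[error]))

    rows = {}
    for src in ("Rep", "ST", "Error_a", "G", "ST x G", "Error_b", "Total"):
        f = p = np.nan
        if src in ("Rep", "ST"):
            f, p = ftest(src, "Error_a")
        elif src in ("G", "ST x G"):
            f, p = ftest(src, "Error_b")
        rows[src] = {
            "df": df[src],
            "ss": ss[src],
            "ms": ms[src] if src != "Total" else np.nan,
            "F": f,
            "p": p,
            "sig": significance_code(p) if np.isfinite(p) else "",
        }
    table = pd.DataFrame(rows).T
    table.index.name = "source"
    table["df"] = table["df"].astype(int)
    return table


def oneway_rcbd_anova(
    data: pd.DataFrame, response: str, rep_col: str = "year", geno_col: str = "genotype"
) -> pd.DataFrame:
    """One-way RCBD ANOVA for genotype effects on per-year STI values.

    Blocks are years (one STI value per genotype per year); used for the
    tolerance indices, which have no within-block replication.
    """
    counts = data.groupby([rep_col, geno_col], observed=True).size()
    r = data[rep_col].nunique()
    g = data[geno_col].nunique()
    if len(counts) != r * g or (counts != 1).any():
        raise ValueError("unbalanced layout for RCBD ANOVA")
    y = data[response].to_numpy(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    m_rep = data.groupby(rep_col, observed=True)[response].mean()
    m_g = data.groupby(geno_col, observed=True)[response].mean()
    ss_rep = g * float(((m_rep - grand) ** 2).sum())
    ss_g = r * float(((m_g - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rep - ss_g, 0.0)
    df = {"Block": r - 1, "G": g - 1, "Error": (r - 1) * (g - 1), "Total": r * g - 1}
    ss = {"Block": ss_rep, "G": ss_g, "Error": ss_err, "Total": ss_total}
    ms = {k: ss[k] / df[k] if df[k] else np.nan for k in df}
    f = ms["G"] / ms["Error"] if ms["Error"] else np.nan
    p = float(stats.f.sf(f, df["G"], df["Error"])) if np.isfinite(f) else np.nan
    rows = {
        k: {
            "df": df[k],
            "ss": ss[k],
            "ms": ms[k] if k != "Total" else np.nan,
            "F": f if k == "G" else np.nan,
            "p": p if k == "G" else np.nan,
            "sig": significance_code(p) if (k == "G" and np.isfinite(p)) else "",
        }
        for k in df
    }
    table = pd.DataFrame(rows).T
    table.index.name = "source"
    table["df"] = table["df"].astype(int)
    return table
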