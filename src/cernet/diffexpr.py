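"""Paired tumor/normal differential expression with moderated t statistics.

The statistic is the empirical-Bayes moderated paired t: per-patient
log2(x+1) tumor-minus-normal differences give an ordinary one-sample t
per gene, and gene-wise variances are shrunk toward a prior (d0, s0^2)
estimated from the distribution of log sample variances by moment
matching against the log-F law, so the moderated t has df + d0 degrees
of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from cernet.datatypes import ExpressionData, log2p1

__all__ = [
    "filter_low_expression",
    "fit_variance_prior",
    "paired_moderated_t",
    "select_de",
]


def filter_low_expression(
    data: ExpressionData, min_mean: float = 1.0, rule: str = "both"
) -> ExpressionData:
    """Drop genes whose mean raw expression falls below ``min_mean``.

    ``rule="both"`` keeps a gene only if its mean is >= min_mean in the
    tumor group AND the normal group; ``rule="either"`` requires only one
    group to pass.
    """
    mean_t = data.tissue_matrix("tumor").mean(axis=1)
    mean_n = data.tissue_matrix("normal").mean(axis=1)
    if rule == "both":
        keep = (mean_t >= min_mean) & (mean_n >= min_mean)
    elif rule == "either":
        keep = (mean_t >= min_mean) | (mean_n >= min_mean)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return data.subset_genes(data.genes[keep.values])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        return np.inf
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-6, 1e8
    if f(lo) < 0:
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0); the mean and
    variance of log s^2 identify the prior via digamma/trigamma.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0sq


def paired_moderated_t(data: ExpressionData, moderate: bool = True) -> pd.DataFrame:
    """Moderated paired t-test of tumor vs normal per gene.

    Returns a table with mean_tumor, mean_normal, log2FC, t, p, q and the
    fitted prior recorded in ``.attrs``. With ``moderate=False`` the
    ordinary paired t is returned (d0 = 0 limit).
    """
    tum, nor = data.paired_matrices()
    n = tum.shape[1]
    if n < 3:
        raise ValueError("need at least 3 complete patient pairs")
    d = log2p1(tum.values) - log2p1(nor.values)
    lfc = d.mean(axis=1)
    df = n - 1
    s2 = d.var(axis=1, ddof=1)

    if moderate:
        d0, s0sq = fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0sq + df * s2) / (d0 + df)
            df_total = df + d0
    else:
        d0, s0sq = 0.0, np.nan
        s2_post = s2
        df_total = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post / n)
    t = np.where(s2_post > 0, t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "type": data.gene_type.loc[tum.index].values,
            "mean_tumor": tum.values.mean(axis=1),
            "mean_normal": nor.values.mean(axis=1),
            "log2FC": lfc,
            "t": t,
            "p": p,
            "q": q,
        },
        index=tum.index,
    )
    table.index.name = "gene"
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s0sq
    table.attrs["residual_df"] = df
    return table


def select_de(
    table: pd.DataFrame,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    rule: str = "and",
) -> tuple[list[str], list[str]]:
    """Call DE genes; returns (lncRNA ids, PCG ids).

    ``rule="and"`` requires p < p_thresh AND |log2FC| > lfc_thresh;
    ``rule="or"`` accepts either condition.
    """
    if table.empty:
        raise ValueError("empty DE table")
    sig_p = table["p"] < p_thresh
    sig_lfc = table["log2FC"].abs() > lfc_thresh
    if rule == "and":
        keep = sig_p & sig_lfc
    elif rule == "or":
        keep = sig_p | sig_lfc
    else:
        raise ValueError(f"unknown rule {rule!r}")
    hits = table[keep]
    lnc = list(hits.index[hits["type"] == "lncRNA"])
    pcg = list(hits.index[hits["type"] == "PCG"])
    return lnc, pcg
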