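"""Prognostic lncRNA signature construction and evaluation.

Per-lncRNA screening uses the maximally selected log-rank statistic
(maxstat) to dichotomize expression; survival-associated candidates then
enter an exhaustive subset search in which every non-empty subset is fit
by Cox regression, patients are split at the median risk score
sum_i x_i * e_i, and the subset with the minimum log-rank p wins. The
final model is evaluated by Kaplan-Meier curves, IPCW time-dependent
ROC AUC at fixed horizons, and univariate/multivariable Cox
independence analysis against age and stage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from cernet.datatypes import ExpressionData, log2p1

logger = logging.getLogger(__name__)

__all__ = [
    "logrank_test",
    "maxstat_cutoff",
    "km_estimate",
    "CoxResult",
    "fit_cox",
    "risk_score",
    "screen_survival_lncRNAs",
    "SignatureModel",
    "exhaustive_signature_search",
    "time_dependent_auc",
    "independence_analysis",
]

Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_statistic(time, event, group) -> tuple[float, float]:
    """Two-group log-rank (O - E)^2 / Var; returns (statistic, variance).

    At each distinct event time the expected group-1 events come from
    the hypergeometric margin d * n1 / n with variance
    d (n1/n) (1 - n1/n) (n - d) / (n - 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be nonempty")
    if event.sum() == 0:
        raise ValueError("no events observed")

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], group[order]
    ev_times = np.unique(t_s[e_s == 1])
    n_total = len(t_s)
    t1 = np.sort(t_s[g_s])

    O_minus_E = 0.0
    V = 0.0
    for tau in ev_times:
        n_at = n_total - np.searchsorted(t_s, tau, side="left")
        n1_at = len(t1) - np.searchsorted(t1, tau, side="left")
        at_tau = t_s == tau
        d = int((e_s[at_tau] == 1).sum())
        d1 = int((e_s[at_tau & g_s] == 1).sum())
        if n_at <= 1:
            continue
        E = d * n1_at / n_at
        O_minus_E += d1 - E
        V += d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    if V <= 0:
        return 0.0, 0.0
    return float(O_minus_E**2 / V), float(V)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    chi2, V = logrank_statistic(time, event, group)
    if V <= 0:
        return 0.0, 1.0
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# maxstat
# ---------------------------------------------------------------------------

def maxstat_cutoff(
    values, time, event, quantile_range: tuple[float, float] = (0.1, 0.9)
) -> tuple[float, float, float, float]:
    """Maximally selected log-rank cutoff for one continuous marker.

    Scans every distinct value within the quantile range as a candidate
    cutoff (group = value > cutoff) and returns
    (cutoff, statistic, p_uncorrected, p_corrected) at the maximum;
    ties prefer the lower cutoff. The corrected p is the
    Lausen-Schumacher improved-Bonferroni approximation honest about
    cutoff selection.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lo, hi = np.quantile(values, quantile_range)
    candidates = np.unique(values)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]

    best = None
    for c in candidates:
        group = values > c
        if group.all() or (~group).all():
            continue
        if event[group].sum() == 0 or event[~group].sum() == 0:
            continue
        chi2, V = logrank_statistic(time, event, group)
        if V <= 0:
            continue
        if best is None or chi2 > best[1]:
            best = (float(c), float(chi2))
    if best is None:
        raise ValueError("no admissible cutoff")
    cutoff, chi2 = best
    p_raw = float(stats.chi2.sf(chi2, df=1))
    p_corr = _lausen_schumacher_p(np.sqrt(chi2), *quantile_range)
    return cutoff, chi2, p_raw, p_corr


def _lausen_schumacher_p(b: float, eps1: float, eps2: float) -> float:
    """Improved-Bonferroni p for the maximally selected statistic."""
    if b <= 1e-8:
        return 1.0
    phi = stats.norm.pdf(b)
    log_term = np.log((eps2 * (1 - eps1)) / (eps1 * (1 - eps2)))
    p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(time, event) -> tuple[pd.DataFrame, float]:
    """Product-limit survival curve and median survival.

    Median is the earliest time with S(t) <= 0.5; NaN (undefined) when
    the curve never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    if time.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event, dtype=int))
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return sf, median


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation: bool
    names: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names or range(len(self.coef)),
        )


class _CoxData:
    """Pre-sorted survival arrays reused across many subset fits."""

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order]
        ev_times = np.unique(self.time[self.event == 1])
        # per distinct event time: (risk-set start index, tied event indices)
        self.groups = []
        for tau in ev_times:
            start = np.searchsorted(self.time, tau, side="left")
            tied = np.where((self.time == tau) & (self.event == 1))[0]
            self.groups.append((start, tied))
        self.n = len(self.time)
        self.has_ties = any(len(tied) > 1 for _, tied in self.groups)
        self.starts = np.array([s for s, _ in self.groups], dtype=np.intp)
        self.event_idx = np.concatenate(
            [tied for _, tied in self.groups]
        ) if self.groups else np.array([], dtype=np.intp)


def _cox_nll_grad_hess(beta, X, data: _CoxData):
    """Negative log partial likelihood with Efron tie handling."""
    k = X.shape[1]
    eta = X @ beta
    eta = eta - eta.max()
    theta = np.exp(eta)
    wX = theta[:, None] * X
    wXX = np.einsum("ni,nj->nij", wX, X)

    # suffix cumulative sums over the time-sorted risk sets
    cs_theta = np.concatenate([np.cumsum(theta[::-1])[::-1], [0.0]])
    cs_wX = np.vstack([np.cumsum(wX[::-1], axis=0)[::-1], np.zeros(k)])
    cs_wXX = np.concatenate(
        [np.cumsum(wXX[::-1], axis=0)[::-1], np.zeros((1, k, k))]
    )

    if not data.has_ties:
        # single event per time: Efron reduces to Breslow, fully vectorized
        ev = data.event_idx
        phi = cs_theta[data.starts]
        mu = cs_wX[data.starts] / phi[:, None]
        nll = float(np.log(phi).sum() - eta[ev].sum())
        grad = mu.sum(axis=0) - X[ev].sum(axis=0)
        hess = (cs_wXX[data.starts] / phi[:, None, None]).sum(axis=0)
        hess -= np.einsum("gi,gj->ij", mu, mu)
        return nll, grad, hess

    nll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    for start, tied in data.groups:
        d = len(tied)
        S_R = cs_theta[start]
        G_R = cs_wX[start]
        S_D = theta[tied].sum()
        G_D = wX[tied].sum(axis=0)
        Xd = X[tied]
        H_R = cs_wXX[start]
        H_D = wXX[tied].sum(axis=0)
        nll -= eta[tied].sum()
        grad -= Xd.sum(axis=0)
        for l in range(d):
            f = l / d
            phi = S_R - f * S_D
            mu = (G_R - f * G_D) / phi
            nll += np.log(phi)
            grad += mu
            hess += (H_R - f * H_D) / phi - np.outer(mu, mu)
    return nll, grad, hess


def fit_cox(
    X, time, event, names: list | None = None, max_iter: int = 60,
    tol: float = 1e-8, data: _CoxData | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson, Efron ties.

    Converges when the gradient infinity-norm drops below ``tol``.
    Complete separation (diverging coefficients) is detected and flagged
    rather than raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if data is None:
        data = _CoxData(time, event)
    if X.shape[0] != data.n:
        raise ValueError("covariate rows must match survival rows")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant covariate column")
    Xs = X[data.order]
    center = Xs.mean(axis=0)
    Xc = Xs - center

    beta = np.zeros(X.shape[1])
    nll, grad, hess = _cox_nll_grad_hess(beta, Xc, data)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        new_beta = beta - step
        new_nll, new_grad, new_hess = _cox_nll_grad_hess(new_beta, Xc, data)
        halves = 0
        while new_nll > nll + 1e-12 and halves < 30:
            step *= 0.5
            new_beta = beta - step
            new_nll, new_grad, new_hess = _cox_nll_grad_hess(new_beta, Xc, data)
            halves += 1
        beta, nll, grad, hess = new_beta, new_nll, new_grad, new_hess
        if np.abs(beta).max() > 15:
            # monotone likelihood: the gradient flattens as beta diverges,
            # so a magnitude guard is the reliable separation signal
            separation = True
            break
        if np.abs(grad).max() < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = beta / se
        hr = np.exp(beta)
        ci_low = np.exp(beta - Z975 * se)
        ci_high = np.exp(beta + Z975 * se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxResult(
        coef=beta,
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        loglik=-nll,
        n_iter=it,
        converged=converged,
        separation=separation,
        names=list(names) if names is not None else [],
    )


# ---------------------------------------------------------------------------
# risk score and screening
# ---------------------------------------------------------------------------

def risk_score(expression: pd.DataFrame, coefs: dict | pd.Series) -> pd.Series:
    """Linear risk score sum_i x_i * e_i on log2(x+1) expression.

    ``expression`` is genes x samples (raw scale); ``coefs`` maps
    signature lncRNA id to its Cox coefficient.
    """
    coefs = pd.Series(coefs, dtype=float)
    missing = [g for g in coefs.index if g not in expression.index]
    if missing:
        raise ValueError(f"signature lncRNA missing from expression: {missing}")
    E = log2p1(expression.loc[coefs.index].values)
    scores = coefs.values @ E
    return pd.Series(scores, index=expression.columns, name="risk_score")


def _aligned_expression(
    expression: ExpressionData | pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Expression columns restricted and ordered to the survival samples."""
    expr = expression.expr if isinstance(expression, ExpressionData) else expression
    missing = [s for s in survival["sample"] if s not in expr.columns]
    if missing:
        raise ValueError(f"survival samples missing from expression: {missing[:5]}")
    return expr[list(survival["sample"])]


def screen_survival_lncRNAs(
    candidates,
    expression,
    survival: pd.DataFrame,
    p_cut: float = 0.05,
    quantile_range: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Per-lncRNA maxstat dichotomization + log-rank screen.

    Returns a table (lncRNA, cutoff, statistic, p, p_corrected, kept);
    lncRNAs whose maxstat scan fails are skipped with a log entry.
    """
    expr = _aligned_expression(expression, survival)
    time = survival["time"].values
    event = survival["event"].values
    rows = []
    for g in candidates:
        if g not in expr.index:
            logger.warning("screen: lncRNA %s not in expression, skipped", g)
            continue
        values = log2p1(expr.loc[g].values)
        try:
            cutoff, chi2, p_raw, p_corr = maxstat_cutoff(
                values, time, event, quantile_range
            )
        except ValueError as exc:
            logger.warning("screen: maxstat failed for %s (%s)", g, exc)
            continue
        rows.append(
            {
                "lncRNA": g,
                "cutoff": cutoff,
                "statistic": chi2,
                "p": p_raw,
                "p_corrected": p_corr,
                "kept": p_raw < p_cut,
            }
        )
    return pd.DataFrame(
        rows, columns=["lncRNA", "cutoff", "statistic", "p", "p_corrected", "kept"]
    )


# ---------------------------------------------------------------------------
# exhaustive signature search
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    lncRNAs: tuple
    coefs: pd.Series
    scores: pd.Series
    cutoff: float
    logrank_stat: float
    logrank_p: float
    group_sizes: tuple
    median_survival: dict
    aucs: dict = field(default_factory=dict)


def _evaluate_subset(subset, E, time, event, cox_data, split):
    res = fit_cox(E[:, list(subset)], time, event, data=cox_data)
    if res.separation or not res.converged:
        return None, res
    scores = E[:, list(subset)] @ res.coef
    if split == "median":
        cutoff = float(np.median(scores))
        group = scores > cutoff
        if group.all() or (~group).all():
            return None, res
        chi2, p = logrank_test(time, event, group)
    elif split == "maxstat":
        cutoff, chi2, p, _ = maxstat_cutoff(scores, time, event)
        group = scores > cutoff
    else:
        raise ValueError(f"unknown split {split!r}")
    return (cutoff, group, chi2, p, scores), res


def exhaustive_signature_search(
    candidates,
    expression,
    survival: pd.DataFrame,
    split: str = "median",
    cox_fitter=None,
    horizons: tuple = (1, 3, 5, 10),
) -> tuple[SignatureModel | None, pd.DataFrame]:
    """Evaluate every non-empty lncRNA subset; best = minimum log-rank p.

    For each of the 2^k - 1 subsets a joint Cox model gives the
    coefficients of the risk score, patients are dichotomized (median
    split by default, per-model maxstat optional) and the two-group
    log-rank p recorded. Ties prefer the smaller subset, then
    lexicographic order. ``cox_fitter`` (same signature as
    :func:`fit_cox`) can replace the Cox step, e.g. to stub it when only
    the enumeration is of interest.

    Returns (best SignatureModel or None, all-models table).
    """
    candidates = list(candidates)
    k = len(candidates)
    if not 1 <= k <= 20:
        raise ValueError("candidate count must lie in [1, 20]")
    expr = _aligned_expression(expression, survival)
    missing = [g for g in candidates if g not in expr.index]
    if missing:
        raise ValueError(f"candidates missing from expression: {missing}")
    E = log2p1(expr.loc[candidates].values).T  # patients x k
    time = survival["time"].values.astype(float)
    event = survival["event"].values.astype(int)
    cox_data = _CoxData(time, event)
    fitter = cox_fitter if cox_fitter is not None else fit_cox

    rows = []
    best_key = None
    best_payload = None
    n_evaluated = 0
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            n_evaluated += 1
            bitmask = sum(1 << i for i in subset)
            names = tuple(candidates[i] for i in subset)
            try:
                if cox_fitter is not None:
                    res = fitter(E[:, list(subset)], time, event)
                    payload = None
                else:
                    payload, res = _evaluate_subset(
                        subset, E, time, event, cox_data, split
                    )
            except ValueError:
                payload, res = None, None
            if payload is None:
                rows.append(
                    {
                        "bitmask": bitmask,
                        "size": size,
                        "lncRNAs": ",".join(names),
                        "coefs": "",
                        "logrank_p": np.nan,
                        "status": "evaluated" if cox_fitter else "failed",
                    }
                )
                continue
            cutoff, group, chi2, p, scores = payload
            rows.append(
                {
                    "bitmask": bitmask,
                    "size": size,
                    "lncRNAs": ",".join(names),
                    "coefs": ",".join(f"{c:.6g}" for c in res.coef),
                    "logrank_p": p,
                    "status": "ok",
                }
            )
            key = (p, size, names)
            if best_key is None or key < best_key:
                best_key = key
                best_payload = (names, res, cutoff, group, chi2, p, scores)

    models = pd.DataFrame(rows)
    models.attrs["n_evaluated"] = n_evaluated
    if best_payload is None:
        return None, models

    names, res, cutoff, group, chi2, p, scores = best_payload
    scores = pd.Series(scores, index=list(survival["sample"]), name="risk_score")
    med = {}
    for label, mask in (("high", group), ("low", ~group)):
        _, m = km_estimate(time[mask], event[mask])
        med[label] = m
    model = SignatureModel(
        lncRNAs=names,
        coefs=pd.Series(res.coef, index=list(names)),
        scores=scores,
        cutoff=cutoff,
        logrank_stat=chi2,
        logrank_p=p,
        group_sizes=(int(group.sum()), int((~group).sum())),
        median_survival=med,
        aucs=time_dependent_auc(scores.values, time, event, horizons),
    )
    return model, models


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

def _censoring_survival_left(time, event, eval_times) -> np.ndarray:
    """KM estimate G(t-) of the censoring distribution, left-continuous."""
    time = np.asarray(time, dtype=float)
    cens = 1 - np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_s, c_s = time[order], cens[order]
    uniq = np.unique(t_s[c_s == 1])
    n = len(t_s)
    factors = []
    for tau in uniq:
        at_risk = n - np.searchsorted(t_s, tau, side="left")
        d = int(c_s[t_s == tau].sum())
        factors.append(1.0 - d / at_risk if at_risk > 0 else 1.0)
    surv = np.cumprod(factors) if factors else np.array([])
    out = np.ones(len(eval_times))
    for i, t in enumerate(np.asarray(eval_times, dtype=float)):
        j = np.searchsorted(uniq, t, side="left")  # strictly before t
        if j > 0:
            out[i] = surv[j - 1]
    return out


def time_dependent_auc(
    scores, time, event, horizons=(1, 3, 5, 10)
) -> dict:
    """Cumulative-case / dynamic-control AUC with IPCW at each horizon.

    Cases at horizon t are patients with an observed event by t, weighted
    by 1/G(T_i-) where G is the KM estimate of the censoring
    distribution; controls are patients still at risk beyond t. Horizons
    with no cases or no controls return NaN.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    G_at_T = _censoring_survival_left(time, event, time)
    out = {}
    for h in horizons:
        cases = (time <= h) & (event == 1)
        controls = time > h
        if cases.sum() == 0 or controls.sum() == 0:
            out[h] = float("nan")
            continue
        w = 1.0 / G_at_T[cases]
        sc = scores[cases][:, None]
        so = scores[controls][None, :]
        wins = (sc > so).astype(float) + 0.5 * (sc == so)
        auc = float((w[:, None] * wins).sum() / (w.sum() * controls.sum()))
        out[h] = auc
    return out


# ---------------------------------------------------------------------------
# independence analysis
# ---------------------------------------------------------------------------

def independence_analysis(
    survival: pd.DataFrame,
    risk_high: pd.Series | np.ndarray,
    age_cut: float = 58.0,
) -> pd.DataFrame:
    """Univariate and multivariable Cox analysis of the signature.

    Covariate codings: age > ``age_cut`` vs <=; stage III/IV vs I/II;
    signature high- vs low-risk. Returns one row per (variable,
    analysis) with HR, 95% CI and Wald p.
    """
    time = survival["time"].values.astype(float)
    event = survival["event"].values.astype(int)
    risk_high = np.asarray(risk_high, dtype=float)
    covs = {
        "age": (survival["age"].values > age_cut).astype(float),
        "stage": survival["stage"].isin(["III", "IV"]).values.astype(float),
        "signature": risk_high,
    }
    comparisons = {
        "age": f">{age_cut:g} vs <={age_cut:g}",
        "stage": "III,IV vs I,II",
        "signature": "high risk vs low risk",
    }
    for name, x in covs.items():
        if event[x == 1].sum() == 0 or event[x == 0].sum() == 0:
            logger.warning("covariate level with zero events: %s", name)

    rows = []
    for name, x in covs.items():
        res = fit_cox(x, time, event, names=[name])
        rows.append(_cox_row(name, comparisons[name], "univariate", res, 0))
    X = np.column_stack(list(covs.values()))
    multi = fit_cox(X, time, event, names=list(covs))
    for i, name in enumerate(covs):
        rows.append(_cox_row(name, comparisons[name], "multivariable", multi, i))
    return pd.DataFrame(rows)


def _cox_row(name, comparison, analysis, res: CoxResult, i: int) -> dict:
    return {
        "variable": name,
        "comparison": comparison,
        "analysis": analysis,
        "HR": float(res.hr[i]),
        "ci_low": float(res.ci_low[i]),
        "ci_high": float(res.ci_high[i]),
        "p": float(res.p[i]),
        "converged": res.converged,
    }
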