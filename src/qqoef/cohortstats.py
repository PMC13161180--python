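"""Group comparisons, interaction regressions and influence diagnostics.

Implements the cohort-level analysis from first principles: OLS via QR,
group x predictor interaction models with an age covariate (AD coded 1,
non-AD 0) and within-group simple slopes as linear contrasts, exact
leave-one-out influence measures (Cook's distance, leverage, DFBETAS),
Benjamini-Hochberg step-up adjustment across ROIs, the Wilcoxon rank-sum
test (exact enumeration for small samples) and Fisher's exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "InfluenceReport",
    "ols_fit",
    "fit_interaction_model",
    "influence_screen",
    "bh_adjust",
    "wilcoxon_ranksum",
    "fisher_exact",
    "residual_diagnostics",
    "analyze_cohort",
]

COEF_NAMES = ("intercept", "beta_pred", "beta_group", "beta_interaction", "beta_age")


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary least squares via QR decomposition.

    Returns (coefficients, coefficient covariance, residuals). Raises on a
    rank-deficient design, naming the collinear columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.where(diag < tol)[0]
    if bad.size:
        raise ValueError(f"rank-deficient design: collinear columns {bad.tolist()}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - x @ beta
    dof = n - k
    if dof <= 0:
        raise ValueError("degrees of freedom must be positive")
    s2 = float(resid @ resid) / dof
    r_inv = np.linalg.solve(r, np.eye(k))
    cov = s2 * (r_inv @ r_inv.T)
    return beta, cov, resid


@dataclass
class RegressionResult:
    """Fitted interaction model with within-group simple slopes."""

    coef: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    simple_slopes: dict[str, dict[str, float]]  # per group: slope, se, t, p
    n: int
    dof: int
    design: np.ndarray = field(repr=False, default=None)
    outcome: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    excluded: list = field(default_factory=list)
    coef_names: tuple = COEF_NAMES


def _t_p(tval: float, dof: int) -> float:
    return float(2.0 * stats.t.sf(abs(tval), dof))


def fit_interaction_model(
    table: pd.DataFrame,
    outcome: str,
    predictor: str = "log_wmh",
    covariates: tuple[str, ...] = ("age",),
    exclude: list | None = None,
) -> RegressionResult:
    """Fit OEF ~ X + group + X:group + age (+ mch) with AD coded 1.

    ``predictor`` is one of {"moca", "wmh", "log_wmh", "log_pwmh",
    "log_dwmh"}; logs are natural. A zero WMH fraction under a log
    predictor raises with advice (offset or exclusion) rather than
    propagating -inf. Simple slopes per group are linear contrasts of the
    combined fit: non-AD = beta_pred, AD = beta_pred + beta_interaction.
    """
    df = table.copy()
    if exclude:
        df = df.drop(index=list(exclude))
    source = {
        "moca": "moca",
        "wmh": "wmh_fraction",
        "log_wmh": "wmh_fraction",
        "log_pwmh": "pwmh_fraction",
        "log_dwmh": "dwmh_fraction",
    }
    if predictor not in source:
        raise ValueError(f"unknown predictor {predictor!r}")
    raw = df[source[predictor]].to_numpy(dtype=float)
    if predictor.startswith("log_"):
        if np.any(raw <= 0):
            raise ValueError(
                "nonpositive WMH fraction under a log predictor; add an offset "
                "(e.g. half the smallest positive value) or exclude those subjects"
            )
        x = np.log(raw)
    else:
        x = raw
    g = (df["group"].astype(str).str.upper() == "AD").to_numpy(dtype=float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("both groups must contain at least 2 subjects")

    cols = [np.ones(len(df)), x, g, x * g]
    names = list(COEF_NAMES[:4])
    for cov_name in covariates:
        cols.append(df[cov_name].to_numpy(dtype=float))
        names.append(f"beta_{cov_name}")
    design = np.column_stack(cols)
    y = df[outcome].to_numpy(dtype=float)
    beta, cov, resid = ols_fit(design, y)
    dof = len(df) - design.shape[1]
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    result = RegressionResult(
        coef=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        t=dict(zip(names, tvals)),
        p={nm: _t_p(t, dof) for nm, t in zip(names, tvals)},
        simple_slopes={},
        n=len(df),
        dof=dof,
        design=design,
        outcome=y,
        residuals=resid,
        cov=cov,
        excluded=list(exclude) if exclude else [],
        coef_names=tuple(names),
    )
    # simple slopes as contrasts of the combined model
    k = design.shape[1]
    for grp, contrast in (("nonAD", [0, 1, 0, 0]), ("AD", [0, 1, 0, 1])):
        c = np.zeros(k)
        c[: 4] = contrast
        slope = float(c @ beta)
        s = math.sqrt(float(c @ cov @ c))
        t = slope / s
        result.simple_slopes[grp] = {
            "slope": slope, "se": s, "t": t, "p": _t_p(t, dof)
        }
    return result


# ---------------------------------------------------------------------------
# Influence diagnostics
# ---------------------------------------------------------------------------

@dataclass
class InfluenceReport:
    """Per-observation influence measures with the three flagging rules."""

    leverage: np.ndarray
    cooks_d: np.ndarray
    dfbetas: np.ndarray  # (n, k)
    cook_threshold: float
    leverage_threshold: float
    dfbeta_threshold: float
    flagged: np.ndarray  # bool per observation (union of rules)
    flagged_cook: np.ndarray
    flagged_leverage: np.ndarray
    flagged_dfbeta: np.ndarray


def influence_measures(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leverage, Cook's distance and DFBETAS by exact leave-one-out identities."""
    x = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
    beta = xtx_inv @ x.T @ y
    e = y - x @ beta
    dof = n - k
    s2 = float(e @ e) / dof
    cooks = (e**2 / (k * s2)) * (hat / (1.0 - hat) ** 2)
    # deleted residual variance s_(i)^2 and standardized coefficient change
    s2_i = (dof * s2 - e**2 / (1.0 - hat)) / (dof - 1)
    s2_i = np.maximum(s2_i, np.finfo(float).tiny)
    delta = (xtx_inv @ x.T).T * (e / (1.0 - hat))[:, None]  # (n, k) coefficient change
    dfbetas = delta / np.sqrt(s2_i[:, None] * np.diag(xtx_inv)[None, :])
    return hat, cooks, dfbetas


def influence_screen(fit: RegressionResult) -> tuple[InfluenceReport, RegressionResult | None]:
    """Flag influential observations and refit without them.

    Thresholds: Cook's distance 4/n, leverage 2(p+1)/n with p the number
    of predictors (so 2k/n with k model coefficients), and |DFBETAS| 2/sqrt(n)
    for any coefficient. The refit excludes the union of flagged rows; if
    exclusion would leave too few observations, an error is raised.
    """
    x, y = fit.design, fit.outcome
    n, k = x.shape
    if n <= k + 2:
        raise ValueError("too few observations for influence screening")
    hat, cooks, dfbetas = influence_measures(x, y)
    thr_cook = 4.0 / n
    thr_lev = 2.0 * k / n  # k = p predictors + 1 intercept = p + 1
    thr_dfb = 2.0 / math.sqrt(n)
    f_cook = cooks > thr_cook
    f_lev = hat > thr_lev
    f_dfb = np.any(np.abs(dfbetas) > thr_dfb, axis=1)
    flagged = f_cook | f_lev | f_dfb
    report = InfluenceReport(
        leverage=hat,
        cooks_d=cooks,
        dfbetas=dfbetas,
        cook_threshold=thr_cook,
        leverage_threshold=thr_lev,
        dfbeta_threshold=thr_dfb,
        flagged=flagged,
        flagged_cook=f_cook,
        flagged_leverage=f_lev,
        flagged_dfbeta=f_dfb,
    )
    refit = None
    keep = ~flagged
    if flagged.any():
        if keep.sum() <= k + 1:
            raise ValueError("excluding influential points leaves too few observations")
        beta, cov, resid = ols_fit(x[keep], y[keep])
        dof = int(keep.sum()) - k
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        names = fit.coef_names
        refit = RegressionResult(
            coef=dict(zip(names, beta)),
            se=dict(zip(names, se)),
            t=dict(zip(names, tvals)),
            p={nm: _t_p(t, dof) for nm, t in zip(names, tvals)},
            simple_slopes={},
            n=int(keep.sum()),
            dof=dof,
            design=x[keep],
            outcome=y[keep],
            residuals=resid,
            cov=cov,
            excluded=np.where(flagged)[0].tolist(),
            coef_names=names,
        )
        for grp, contrast in (("nonAD", [0, 1, 0, 0]), ("AD", [0, 1, 0, 1])):
            c = np.zeros(k)
            c[:4] = contrast
            slope = float(c @ beta)
            s = math.sqrt(float(c @ cov @ c))
            t = slope / s
            refit.simple_slopes[grp] = {"slope": slope, "se": s, "t": t, "p": _t_p(t, dof)}
    return report, refit


# ---------------------------------------------------------------------------
# Multiple testing, rank and exact tests
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; exact enumeration for small n.

    Mid-ranks handle ties. For combined sample size <= 12 the null
    distribution of the rank sum is enumerated exhaustively over all group
    assignments; otherwise the tie-corrected normal approximation with
    continuity correction is used. Returns (rank-sum statistic of the
    first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * (len(pooled) + 1) / 2.0), 1.0
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    w = float(ranks[:n1].sum())
    if n <= 12:
        sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n1)])
        mu = float(sums.mean())
        p = float((np.abs(sums - mu) >= abs(w - mu) - 1e-12).mean())
        return w, min(p, 1.0)
    mu = n1 * (n + 1) / 2.0
    n2 = n - n1
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return w, float(min(2.0 * stats.norm.sf(max(z, 0.0)), 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Enumerates the hypergeometric distribution of the top-left cell and
    sums the probabilities of all tables at most as probable as the one
    observed (probability-mass criterion). An empty margin gives p = 1
    with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    r1, r2 = t.sum(axis=1)
    c1, _ = t.sum(axis=0)
    n = int(t.sum())
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("empty margin; Fisher p defined as 1")
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    if p >= 1.0 - 1e-9:  # whole support included; probabilities sum to one
        return 1.0
    return max(p, np.finfo(float).tiny)


def residual_diagnostics(fit: RegressionResult) -> dict[str, float]:
    """Heteroscedasticity screen: |residual|-vs-fitted slope and spread ratio.

    The spread ratio compares residual variance in the upper versus lower
    half of fitted values; values far from 1 indicate variance trending
    with the mean.
    """
    fitted = fit.design @ np.array([fit.coef[nm] for nm in fit.coef_names])
    resid = fit.residuals
    if np.allclose(resid, 0.0):
        return {"trend_slope": 0.0, "spread_ratio": 1.0}
    x = np.column_stack([np.ones_like(fitted), fitted])
    slope = float(np.linalg.lstsq(x, np.abs(resid), rcond=None)[0][1])
    med = np.median(fitted)
    lo, hi = resid[fitted <= med], resid[fitted > med]
    v_lo = float(np.var(lo, ddof=1)) if len(lo) > 1 else 0.0
    v_hi = float(np.var(hi, ddof=1)) if len(hi) > 1 else 0.0
    ratio = v_hi / v_lo if v_lo > 0 else float("inf")
    return {"trend_slope": slope, "spread_ratio": ratio}


# ---------------------------------------------------------------------------
# Tidy cohort analysis driver
# ---------------------------------------------------------------------------

def influence_table(
    table: pd.DataFrame,
    predictor: str = "log_wmh",
    covariates: tuple[str, ...] = ("age",),
    rois: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Long-format per-observation influence report across ROIs.

    One row per (ROI, subject) with leverage, Cook's distance, the maximal
    |DFBETAS| over coefficients, the three thresholds and their flags.
    """
    if rois is None:
        rois = tuple(c[4:] for c in table.columns if c.startswith("oef_"))
    rows = []
    for roi in rois:
        fit = fit_interaction_model(table, f"oef_{roi}", predictor, covariates)
        rep, _ = influence_screen(fit)
        for i in range(fit.n):
            rows.append({
                "roi": roi,
                "subject": table.iloc[i].get("subject", i),
                "leverage": rep.leverage[i],
                "cooks_d": rep.cooks_d[i],
                "max_abs_dfbetas": float(np.abs(rep.dfbetas[i]).max()),
                "cook_threshold": rep.cook_threshold,
                "leverage_threshold": rep.leverage_threshold,
                "dfbeta_threshold": rep.dfbeta_threshold,
                "flag_cook": bool(rep.flagged_cook[i]),
                "flag_leverage": bool(rep.flagged_leverage[i]),
                "flag_dfbeta": bool(rep.flagged_dfbeta[i]),
                "flagged": bool(rep.flagged[i]),
            })
    return pd.DataFrame(rows)


def analyze_cohort(
    table: pd.DataFrame,
    predictor: str = "log_wmh",
    covariates: tuple[str, ...] = ("age",),
    rois: tuple[str, ...] | None = None,
    exclude_influential: bool = False,
    bh: bool = True,
) -> pd.DataFrame:
    """Per-ROI interaction regressions with optional influence exclusion and BH.

    Returns a tidy frame: one row per ROI with coefficients, p-values,
    within-group simple slopes and (when ``bh``) adjusted p-values across
    the ROI family, separately per reported p-value column.
    """
    if rois is None:
        rois = tuple(c[4:] for c in table.columns if c.startswith("oef_"))
    rows = []
    for roi in rois:
        fit = fit_interaction_model(table, f"oef_{roi}", predictor, covariates)
        n_excluded = 0
        if exclude_influential:
            _, refit = influence_screen(fit)
            if refit is not None:
                n_excluded = len(refit.excluded)
                fit = refit
                if not fit.simple_slopes:
                    pass
        row = {"roi": roi, "n": fit.n, "n_excluded": n_excluded}
        for nm in fit.coef_names:
            row[nm] = fit.coef[nm]
            row[f"p_{nm}"] = fit.p[nm]
        for grp in ("AD", "nonAD"):
            ss = fit.simple_slopes[grp]
            row[f"slope_{grp}"] = ss["slope"]
            row[f"p_slope_{grp}"] = ss["p"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh:
        for col in ("p_beta_interaction", "p_slope_AD", "p_slope_nonAD"):
            out[f"{col}_bh"] = bh_adjust(out[col].to_numpy())
    return out
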