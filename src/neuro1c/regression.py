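"""Multivariable linear models with group-specific residual variance.

The differential metabolite analysis fits, per metabolite, a linear model of
the control-standardised z-value on group indicators and covariates while
letting the residual variance differ by subject group (estimated jointly
with the coefficients by maximum likelihood — iterated weighted least
squares on the profiled variances).  Collinearity diagnostics (pairwise
Pearson r, adjusted generalized variance-inflation factors), multiplicity
control (Benjamini-Hochberg, Storey q-values), and the association-table
drivers for group contrasts and added-covariate associations live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neuro1c.synthetic import COMORBIDITIES


class RegressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Heteroscedastic (group-variance) linear model
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """ML fit of y = X beta + e with Var(e_i) = sigma^2 * m_{g(i)}.

    ``variance_multipliers`` are relative residual variances per group with
    the reference group fixed at 1; with a single variance group the fit
    coincides with ordinary least squares.  Wald t-tests use df = n - p.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    sigma2: float
    variance_multipliers: dict
    loglik: float
    converged: bool
    n_iter: int


def fit_group_hetero_lm(
    y,
    X: pd.DataFrame,
    variance_groups=None,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RegressionFit:
    """Maximum-likelihood linear regression with per-group residual variance.

    Iterates (1) weighted least squares for beta given the group variances
    and (2) the closed-form ML update sigma_g^2 = RSS_g / n_g, until the
    relative log-likelihood change falls below ``tol``.  The first group (in
    order of appearance) is the reference; multipliers are reported relative
    to it.
    """
    y = np.asarray(y, float)
    names = list(X.columns)
    Xm = X.to_numpy(float)
    n, p = Xm.shape
    if variance_groups is None:
        groups = np.zeros(n, int)
        levels = [0]
    else:
        vg = pd.Series(np.asarray(variance_groups), dtype="object")
        levels = list(dict.fromkeys(vg))
        groups = vg.map({g: i for i, g in enumerate(levels)}).to_numpy(int)
    k = len(levels)
    if n <= p + k:
        raise RegressionError(f"n={n} too small for p={p} terms and {k} variance groups")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(Xm)):
        raise RegressionError("non-finite values in response or design")
    if np.linalg.matrix_rank(Xm) < p:
        # name the aliased columns for the error message
        _, r = np.linalg.qr(Xm)
        aliased = [names[j] for j in range(p) if abs(r[j, j]) < 1e-10]
        raise RegressionError(f"rank-deficient design; aliased terms: {aliased}")

    sigma2_g = np.ones(k)
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / sigma2_g[groups]
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xm * sw[:, None], y * sw, rcond=None)
        resid = y - Xm @ beta
        for g in range(k):
            m = groups == g
            sigma2_g[g] = max(float(resid[m] @ resid[m] / m.sum()), 1e-300)
        new_ll = -0.5 * (n * np.log(2 * np.pi)
                         + float(np.sum(np.log(sigma2_g[groups])))
                         + float(np.sum(resid**2 / sigma2_g[groups])))
        if abs(new_ll - loglik) <= tol * (abs(loglik) + 1.0):
            loglik = new_ll
            converged = True
            break
        loglik = new_ll
    w = 1.0 / sigma2_g[groups]
    XtWX = Xm.T @ (Xm * w[:, None])
    cov = np.linalg.inv(XtWX)
    beta = cov @ (Xm.T @ (y * w))
    df = n - p
    # ML residual variances divide by n_g; rescale the Wald covariance by
    # n/(n-p) so the single-group case reproduces the OLS standard errors
    se = np.sqrt(np.diag(cov) * n / df)
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    ref = sigma2_g[0]
    return RegressionFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(pvals, index=names),
        df_resid=df,
        sigma2=float(ref),
        variance_multipliers={g: float(sigma2_g[i] / ref) for i, g in enumerate(levels)},
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Collinearity diagnostics
# ---------------------------------------------------------------------------

def pearson_collinearity(X: pd.DataFrame) -> float:
    """Maximum absolute pairwise Pearson correlation among regressors
    (constant columns are excluded with a warning)."""
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = set(X.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant columns excluded from collinearity check: {sorted(dropped)}")
    if len(keep) < 2:
        raise RegressionError("need >= 2 non-constant regressors")
    r = np.corrcoef(X[keep].to_numpy(float), rowvar=False)
    np.fill_diagonal(r, 0.0)
    return float(np.max(np.abs(r)))


def adjusted_gvif(X: pd.DataFrame, term_groups: dict) -> pd.Series:
    """Adjusted generalized variance-inflation factor per model term.

    For a term occupying columns S of the (centred) design, GVIF =
    det(R_S) * det(R_-S) / det(R) on the regressor correlation matrix, and
    the adjusted value is GVIF^(1/(2 df)) with df = |S| — comparable across
    terms of different dimension.
    """
    cols = list(X.columns)
    R = np.corrcoef(X.to_numpy(float), rowvar=False)
    if not np.all(np.isfinite(R)):
        raise RegressionError("correlation matrix undefined (constant column?)")
    det = np.linalg.det
    detR = det(R)
    if abs(detR) < 1e-12:
        raise RegressionError("rank-deficient design in GVIF computation")
    out = {}
    for term, members in term_groups.items():
        idx = [cols.index(c) for c in members]
        rest = [i for i in range(len(cols)) if i not in idx]
        g = det(R[np.ix_(idx, idx)]) * det(R[np.ix_(rest, rest)]) / detR
        out[term] = float(g) ** (1.0 / (2.0 * len(idx)))
    return pd.Series(out, name="adjusted_gvif")


# ---------------------------------------------------------------------------
# Multiple-testing control
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs are excluded from
    the family size and propagated."""
    p = np.asarray(pvalues, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def storey_pi0(pvalues, lambdas=None) -> float:
    """Storey's smoother estimate of the null proportion pi0: the natural
    cubic trend of pi0(lambda) = #{p > lambda} / (m (1 - lambda)) evaluated
    at the largest lambda of the grid, clamped to (0, 1]."""
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(pvalues, *, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0 x the BH step-up quantity, monotone in ranked p.

    With ``pi0`` forced to 1 the output equals Benjamini-Hochberg exactly.
    Families smaller than 20 fall back to BH with a warning (pi0 estimation
    is unstable there).
    """
    p = np.asarray(pvalues, float)
    ok = np.isfinite(p)
    if ok.sum() < 20 and pi0 is None:
        warnings.warn("fewer than 20 p-values; falling back to BH for q-values")
        return bh_adjust(p)
    if pi0 is None:
        pi0 = storey_pi0(p[ok])
    out = np.full_like(p, np.nan)
    out[ok] = np.minimum(pi0 * _bh_raw(p[ok]), 1.0)
    return out


def _bh_raw(p: np.ndarray) -> np.ndarray:
    """BH step-up quantity min_{j>=i} m p_(j) / j without the cap interacting
    with the pi0 factor (capping is applied by the caller)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = ranked
    return out


# ---------------------------------------------------------------------------
# Design construction and association drivers
# ---------------------------------------------------------------------------

#: Default covariate columns entering every model (after imputation):
#: demographics, comorbidity flags, acute-levodopa indicators, and the
#: log-transformed tissue-handling covariates (log capture of exponential
#: post-mortem / storage decay).
DEFAULT_COVARIATES = ("age", "sex_male", "education", "bmi",
                      *COMORBIDITIES, "dopa_pdd", "dopa_pdnd",
                      "log_pmi", "log_storage")


@dataclass
class DesignSpec:
    """Which group indicators and covariates enter the model.

    ``group_merges`` maps a contrast name to the set of groups sharing one
    indicator (e.g. ``{"Dementia": ("PD-D", "AD-D")}``); unmerged non-control
    groups get their own indicator.  The control group is the reference.
    """

    control_group: str = "HC-CN"
    group_merges: dict = field(default_factory=dict)
    covariates: tuple = DEFAULT_COVARIATES
    variance_by_group: bool = True


def build_design(subjects: pd.DataFrame, spec: DesignSpec) -> tuple[pd.DataFrame, list]:
    """Intercept + group indicators + covariates design matrix from a
    subject table (expects derived columns sex_male, log_pmi, log_storage,
    dopa_pdd, dopa_pdnd to be present where used).  Returns (X, group_terms)."""
    X = pd.DataFrame(index=subjects.index)
    X["const"] = 1.0
    merged = {g for gs in spec.group_merges.values() for g in gs}
    group_terms = []
    for name, gs in spec.group_merges.items():
        X[name] = subjects["group"].isin(gs).astype(float)
        group_terms.append(name)
    for g in subjects["group"].unique():
        if g == spec.control_group or g in merged:
            continue
        X[g] = (subjects["group"] == g).astype(float)
        group_terms.append(g)
    for c in spec.covariates:
        if c in subjects.columns:
            X[c] = subjects[c].astype(float)
    return X, group_terms


def prepare_covariates(subjects: pd.DataFrame,
                       dopa_indicators: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derive the model-ready covariate columns: male indicator, log PMI,
    log storage, and the acute-levodopa indicators (zeros when no DOPA data
    is supplied)."""
    out = subjects.copy()
    out["sex_male"] = (out["sex"] == "M").astype(float)
    out["log_pmi"] = np.log(out["pmi_hours"].astype(float))
    out["log_storage"] = np.log(out["storage_years"].astype(float))
    if dopa_indicators is not None:
        di = dopa_indicators.reset_index(drop=True)
        out = out.reset_index(drop=True)
        out[["dopa_pdd", "dopa_pdnd"]] = di[["dopa_pdd", "dopa_pdnd"]].to_numpy()
    else:
        out["dopa_pdd"] = 0.0
        out["dopa_pdnd"] = 0.0
    return out


def run_differential(z: pd.DataFrame, subjects: pd.DataFrame,
                     spec: DesignSpec | None = None) -> pd.DataFrame:
    """Per-metabolite group-contrast association table.

    One heteroscedastic (group-variance) model per metabolite with the
    standardised value as the response; group-term p-values are BH-adjusted
    across metabolites within each contrast term (one family per term).
    Returns columns response, term, beta, se, p, fdr, converged.
    """
    spec = spec or DesignSpec()
    X, group_terms = build_design(subjects, spec)
    vgroups = subjects["group"].to_numpy() if spec.variance_by_group else None
    rows = []
    for met in z.columns:
        y = z[met].to_numpy(float)
        if not np.all(np.isfinite(y)):
            continue
        fit = fit_group_hetero_lm(y, X, vgroups)
        for term in group_terms:
            rows.append({"response": met, "term": term,
                         "beta": fit.params[term], "se": fit.bse[term],
                         "p": fit.pvalues[term], "converged": fit.converged})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = np.nan
        for term in table["term"].unique():
            m = table["term"] == term
            table.loc[m, "fdr"] = bh_adjust(table.loc[m, "p"].to_numpy())
    return table


def run_covariate_response_assoc(
    y: pd.Series | np.ndarray,
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    spec: DesignSpec | None = None,
    *,
    subset_mask=None,
) -> pd.DataFrame:
    """Association of a response (progression score, Hcy, betaine, ...) with
    each feature added one at a time to the full adjusted model.

    Returns one row per feature with the added term's beta, p, and BH FDR
    across the feature family.  ``subset_mask`` restricts to a subgroup;
    subsets too small for the design are skipped with a warning.
    """
    spec = spec or DesignSpec()
    X, _ = build_design(subjects, spec)
    y = np.asarray(y, float)
    mask = np.ones(len(y), bool) if subset_mask is None else np.asarray(subset_mask, bool)
    vg_all = subjects["group"].to_numpy() if spec.variance_by_group else None
    rows = []
    for feat in features.columns:
        Xf = X.copy()
        Xf[feat] = np.asarray(features[feat], float)
        Xs, ys = Xf.loc[mask], y[mask]
        Xs = Xs.loc[:, (Xs.nunique() > 1) | (Xs.columns == "const")]
        vg = vg_all[mask] if vg_all is not None else None
        k = len(np.unique(vg)) if vg is not None else 1
        if mask.sum() <= Xs.shape[1] + k:
            warnings.warn(f"subset too small for feature {feat!r}; skipped")
            continue
        fit = fit_group_hetero_lm(ys, Xs, vg)
        rows.append({"feature": feat, "beta": fit.params[feat],
                     "se": fit.bse[feat], "p": fit.pvalues[feat],
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table
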