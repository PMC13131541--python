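"""SNP association scans, inheritance-model selection, and linkage
disequilibrium.

Group scans use Wilcoxon-Mann-Whitney tests on the ordinal allele counts
(0/1/2), with an exact permutation p-value at small sample sizes and the
tie-corrected normal approximation otherwise.  Per-SNP effects on a
quantitative response are modelled after choosing among dominant, recessive
and additive codings by BIC (all three carry the same parameter count, so
the comparison reduces to likelihood).  Two-locus LD statistics (D, D', r)
come from EM haplotype-frequency estimation on unphased genotypes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from neuro1c.regression import bh_adjust, storey_qvalues


class SNPAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney
# ---------------------------------------------------------------------------

def _wmw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the rank-sum statistic:
    enumerates every assignment of the pooled values to group A and counts
    arrangements with |W - E[W]| at least as extreme as observed."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    mu = na * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mu) - 1e-12
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(comb)].sum()
        count += abs(w - mu) >= dev_obs
        total += 1
    return count / total


def wmw_group_test(values_a, values_b, *, exact_max_n: int = 16) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value comparing two groups of
    allele counts: exact permutation enumeration when the pooled size is at
    most ``exact_max_n``, otherwise the tie-corrected normal approximation.
    All-tied data gives p = 1."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise SNPAnalysisError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0
    if len(a) + len(b) <= exact_max_n:
        return _wmw_exact_p(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def genotype_frequencies(g) -> dict:
    """Heterozygote / homozygote-mutant percentages of a genotype vector."""
    g = np.asarray(g, float)
    g = g[np.isfinite(g)]
    n = len(g)
    return {"het_pct": 100.0 * (g == 1).sum() / n if n else np.nan,
            "hm_pct": 100.0 * (g == 2).sum() / n if n else np.nan}


def snp_subgroup_scan(genotypes: pd.DataFrame, groups: pd.Series,
                      comparisons: dict) -> pd.DataFrame:
    """WMW scan of every SNP over a set of named group comparisons.

    ``comparisons`` maps a name to a pair of group-label collections, e.g.
    ``{"PD-D vs PD-CN": (("PD-D",), ("PD-CN",))}``.  q-values are computed
    across the whole scan; per-group Het/Hm frequency summaries are attached.
    """
    groups = groups.reindex(genotypes.index)
    rows = []
    for name, (ga, gb) in comparisons.items():
        mask_a = groups.isin(ga).to_numpy()
        mask_b = groups.isin(gb).to_numpy()
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            warnings.warn(f"comparison {name!r} has an empty side; skipped")
            continue
        for snp in genotypes.columns:
            g = genotypes[snp].to_numpy(float)
            row = {"snp": snp, "comparison": name,
                   "p": wmw_group_test(g[mask_a], g[mask_b])}
            row.update({f"a_{k}": v for k, v in genotype_frequencies(g[mask_a]).items()})
            row.update({f"b_{k}": v for k, v in genotype_frequencies(g[mask_b]).items()})
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table["q"] = storey_qvalues(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Inheritance-model selection
# ---------------------------------------------------------------------------

MODELS = ("dominant", "recessive", "additive")


def inheritance_coding(g: np.ndarray, model: str) -> np.ndarray:
    """Numeric SNP coding under an inheritance model: dominant = carrier
    indicator [g >= 1], recessive = homozygote indicator [g == 2],
    additive = allele count g."""
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g == 2).astype(float)
    if model == "additive":
        return g.astype(float)
    raise SNPAnalysisError(f"unknown inheritance model {model!r}")


@dataclass
class InheritanceFit:
    """Minimum-BIC inheritance model for one SNP with the chosen model's
    effect estimate.  All three codings have equal parameter counts, so BIC
    ranking reduces to likelihood ranking; ties prefer additive, then
    dominant."""

    model: str
    bic: dict
    beta: float
    se: float
    p: float


def choose_inheritance_model(genotype, y, covariates: pd.DataFrame) -> InheritanceFit:
    """Fit y ~ coding(g) + covariates under each inheritance coding by OLS
    and return the model minimising BIC.

    The recessive coding is dropped when no homozygote-mutant subject is
    present (constant indicator).  Rows with missing genotype or response
    are excluded pairwise.
    """
    g = np.asarray(genotype, float)
    y = np.asarray(y, float)
    ok = np.isfinite(g) & np.isfinite(y)
    g, y = g[ok], y[ok]
    C = covariates.loc[np.asarray(ok)] if len(covariates) == len(ok) else covariates
    C = C.reset_index(drop=True)
    if np.ptp(y) == 0:
        # constant response: every coding fits perfectly, BICs are degenerate
        # ties -> additive by convention
        return InheritanceFit(model="additive",
                              bic={m: 0.0 for m in MODELS},
                              beta=0.0, se=0.0, p=1.0)

    candidates = []
    for model in MODELS:
        x = inheritance_coding(g, model)
        if np.unique(x).size < 2:
            continue
        X = sm.add_constant(C.assign(_snp=x), has_constant="add")
        fit = sm.OLS(y, X.astype(float)).fit()
        candidates.append((model, fit))
    if not candidates:
        raise SNPAnalysisError("no identifiable inheritance coding (monomorphic SNP)")
    bics = {m: float(f.bic) for m, f in candidates}
    best = min(bics.values())
    # tie-break among models within numerical tolerance: additive > dominant > recessive
    priority = {"additive": 0, "dominant": 1, "recessive": 2}
    tied = [m for m, b in bics.items() if b <= best + 1e-6]
    model = min(tied, key=lambda m: priority[m])
    fit = dict(candidates)[model]
    return InheritanceFit(model=model, bic=bics,
                          beta=float(fit.params["_snp"]),
                          se=float(fit.bse["_snp"]),
                          p=float(fit.pvalues["_snp"]))


def snp_metabolite_assoc(
    genotypes: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame,
    *,
    exclude_mask=None,
    metabolite_kind: str = "Hcy",
) -> pd.DataFrame:
    """Per-SNP association with a metabolite (Hcy or betaine) under the
    per-SNP BIC-chosen inheritance model.

    ``exclude_mask`` removes subjects (e.g. acute levodopa presence) before
    fitting.  Direction labels feed the composite scores: a SNP is labelled
    ``risk`` when it raises Hcy or lowers betaine, ``protective`` for the
    converse.  q-values are computed across the SNP family.
    """
    if metabolite_kind not in ("Hcy", "betaine"):
        raise SNPAnalysisError("metabolite_kind must be 'Hcy' or 'betaine'")
    keep = np.ones(len(y), bool)
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, bool)
    rows = []
    for snp in genotypes.columns:
        g = genotypes[snp].to_numpy(float)[keep]
        try:
            fit = choose_inheritance_model(
                g, np.asarray(y, float)[keep], covariates.loc[keep].reset_index(drop=True))
        except SNPAnalysisError:
            continue
        raises_y = fit.beta > 0
        risk = raises_y if metabolite_kind == "Hcy" else not raises_y
        rows.append({"snp": snp, "model": fit.model, "beta": fit.beta,
                     "se": fit.se, "p": fit.p,
                     "direction": "risk" if risk else "protective"})
    table = pd.DataFrame(rows)
    if len(table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table["q"] = storey_qvalues(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _two_locus_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under haplotype
    frequencies f = (ab, aB, Ab, AB) with random mating."""
    probs = np.zeros((3, 3))
    hap = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for i, (ai, bi) in enumerate(hap):
        for j, (aj, bj) in enumerate(hap):
            probs[ai + aj, bi + bj] += f[i] * f[j]
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(ll.sum())


def estimate_haplotypes_em(g1, g2, *, tol: float = 1e-10,
                           max_iter: int = 1000,
                           return_history: bool = False):
    """ML two-locus haplotype frequencies (ab, aB, Ab, AB) from unphased
    genotypes by EM over the double-heterozygote phase ambiguity.

    With no double heterozygotes the estimate equals direct haplotype
    counting.  Pairs with a missing genotype are dropped.  With
    ``return_history`` the per-iteration log-likelihood trajectory is
    returned alongside the frequencies (it is non-decreasing, the EM
    guarantee).
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    n = len(g1)
    if n < 5:
        raise SNPAnalysisError("need >= 5 informative subjects for haplotype EM")
    # fixed haplotype contributions for the nine genotype combinations,
    # except the double heterozygote whose two phasings are weighted in EM
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    base = np.zeros(4)  # ab, aB, Ab, AB
    det_pairs = {
        (0, 0): (0, 0), (0, 1): (0, 1), (0, 2): (1, 1),
        (1, 0): (0, 2), (1, 2): (1, 3),
        (2, 0): (2, 2), (2, 1): (2, 3), (2, 2): (3, 3),
    }
    for (a, b), (h1, h2) in det_pairs.items():
        c = counts[a, b]
        base[h1] += c
        base[h2] += c
    n_dh = counts[1, 1]
    f = np.full(4, 0.25)
    history = []
    for _ in range(max_iter):
        # E: split double heterozygotes between cis (ab/AB) and trans (aB/Ab)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = base.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= 2.0 * n
        if return_history:
            history.append(_two_locus_loglik(counts, new))
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    if return_history:
        return f, history
    return f


@dataclass
class LDResult:
    """Two-locus LD summary: haplotype frequencies (ab, aB, Ab, AB with
    capital = minor allele), signed D = f_AB - p q, D' = |D| / Dmax with the
    sign-appropriate bound (reported as a magnitude; the sign lives in
    ``phase``), correlation r, and the chi-square test 2 N r^2 on 1 df."""

    haplotype_freqs: np.ndarray
    D: float
    Dprime: float
    phase: str
    r: float
    chi2: float
    p: float
    n: int


def ld_stats(g1, g2) -> LDResult:
    """Estimate D, D', r and the association test for two SNPs from
    unphased genotypes (EM haplotype frequencies)."""
    g1a = np.asarray(g1, float)
    g2a = np.asarray(g2, float)
    ok = np.isfinite(g1a) & np.isfinite(g2a)
    if np.unique(g1a[ok]).size < 2 or np.unique(g2a[ok]).size < 2:
        raise SNPAnalysisError("LD undefined for a monomorphic locus")
    f = estimate_haplotypes_em(g1a, g2a)
    p1 = f[2] + f[3]  # minor-allele frequency, locus 1
    q1 = f[1] + f[3]  # minor-allele frequency, locus 2
    D = f[3] - p1 * q1
    if D >= 0:
        dmax = min(p1 * (1 - q1), (1 - p1) * q1)
    else:
        dmax = min(p1 * q1, (1 - p1) * (1 - q1))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    denom = p1 * (1 - p1) * q1 * (1 - q1)
    r = D / np.sqrt(denom) if denom > 0 else 0.0
    n = int(ok.sum())
    chi2 = 2.0 * n * r * r
    p = float(stats.chi2.sf(chi2, 1))
    return LDResult(haplotype_freqs=f, D=float(D), Dprime=float(dprime),
                    phase="coupling" if D >= 0 else "repulsion",
                    r=float(r), chi2=float(chi2), p=p, n=n)
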