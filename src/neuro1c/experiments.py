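"""Reproducible benchmark experiments over the pipeline.

Each function sets up a synthetic experiment at a stated problem size, runs
the relevant pipeline stages, and returns measured quantities: analytic
constants, agreement gaps against independent oracle computations,
parameter-recovery and calibration rates, LD behaviour and expression-tree
classifier behaviour.  They are consumed by the acceptance script and the
test suite.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from neuro1c import gp, preprocessing, regression, scores, snp, synthetic
from neuro1c.preprocessing import LOD_MULTIPLIER
from neuro1c.scores import VITAMIN_Z_THRESHOLD


def analytic_constants() -> dict:
    """The two analytic constants of the preprocessing/score conventions:
    the blank-LOD multiplier (inverse normal CDF at 0.999) and the deficient-
    vitamin z threshold (inverse normal CDF at 0.05), at printed precision."""
    return {
        "lod_multiplier": round(float(stats.norm.ppf(0.999)), 2),
        "lod_multiplier_used": round(LOD_MULTIPLIER, 2),
        "vitamin_z_threshold": round(float(stats.norm.ppf(0.05)), 2),
        "vitamin_z_threshold_used": round(VITAMIN_Z_THRESHOLD, 2),
    }


# ---------------------------------------------------------------------------
# Oracle equivalences
# ---------------------------------------------------------------------------

def hetero_vs_ols_gap(seed: int = 0, n: int = 200) -> float:
    """Max |beta difference| between the heteroscedastic ML fit with a
    single variance group and the ordinary-least-squares oracle."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n),
                      "x2": rng.normal(size=n)})
    y = 1.0 + 0.5 * X["x1"] - 0.3 * X["x2"] + rng.normal(size=n)
    fit = regression.fit_group_hetero_lm(y, X)
    ols = sm.OLS(np.asarray(y), X).fit()
    return float(np.max(np.abs(fit.params.to_numpy() - ols.params.to_numpy())))


def wmw_asymptotic_vs_exact_gap(n_datasets: int = 200, seed: int = 0,
                                n_per_group: int = 8) -> float:
    """Max |p difference| between the continuity-corrected normal
    approximation and exact permutation enumeration on random continuous
    datasets at n = 8 + 8.

    Tie-free data is the regime where the approximation is expected to
    track the exact distribution; with heavily tied ordinal data the exact
    null is coarse and no asymptotic formula tracks it closely, which is
    precisely why the implementation switches to exact enumeration at small
    n.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        exact = snp._wmw_exact_p(a, b)
        asym = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)
        worst = max(worst, abs(exact - asym))
    return worst


def em_vs_counting_gap(seed: int = 0) -> float:
    """Max |haplotype-frequency difference| between the EM estimator and
    direct haplotype counting on data without double heterozygotes (where
    phase is unambiguous and counting is exact)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    combos = [(a, b) for a in range(3) for b in range(3) if not (a == b == 1)]
    pairs = {(0, 0): (0, 0), (0, 1): (0, 1), (0, 2): (1, 1), (1, 0): (0, 2),
             (1, 2): (1, 3), (2, 0): (2, 2), (2, 1): (2, 3), (2, 2): (3, 3)}
    for _ in range(50):
        idx = rng.integers(0, len(combos), 30)
        g1 = np.array([combos[i][0] for i in idx], float)
        g2 = np.array([combos[i][1] for i in idx], float)
        counts = np.zeros(4)
        for a, b in zip(g1.astype(int), g2.astype(int)):
            h1, h2 = pairs[(a, b)]
            counts[h1] += 1
            counts[h2] += 1
        oracle = counts / counts.sum()
        est = snp.estimate_haplotypes_em(g1, g2)
        worst = max(worst, float(np.max(np.abs(est - oracle))))
    return worst


def gvif_vs_bruteforce_gap(seed: int = 0) -> float:
    """Max |adjusted-GVIF difference| against a brute-force oracle that uses
    covariance-matrix determinants (an algebraically equivalent but
    independently coded route) on a correlated design with a 3-level factor."""
    rng = np.random.default_rng(seed)
    n = 300
    f = rng.integers(0, 3, n)
    x = rng.normal(size=n) + 0.8 * (f == 2)
    z = rng.normal(size=n)
    X = pd.DataFrame({"f1": (f == 1).astype(float), "f2": (f == 2).astype(float),
                      "x": x, "z": z})
    terms = {"f": ["f1", "f2"], "x": ["x"], "z": ["z"]}
    ours = regression.adjusted_gvif(X, terms)
    S = np.cov(X.to_numpy(float), rowvar=False)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    det = np.linalg.det
    cols = list(X.columns)
    worst = 0.0
    for t, members in terms.items():
        i1 = [cols.index(c) for c in members]
        i2 = [i for i in range(len(cols)) if i not in i1]
        g = det(R[np.ix_(i1, i1)]) * det(R[np.ix_(i2, i2)]) / det(R)
        worst = max(worst, abs(ours[t] - g ** (1.0 / (2 * len(i1)))))
    return float(worst)


def bh_vs_stepup_gap(seed: int = 0, m: int = 500) -> float:
    """Max |difference| between the BH adjustment used by the pipeline and a
    literal step-up implementation of the definition."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=m)
    ours = regression.bh_adjust(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return float(np.max(np.abs(ours - adj)))


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def _pipeline_beta(seed: int, effect: float = -0.73, metabolite: str = "biotin",
                   group: str = "AD-D") -> float:
    """One full simulate -> preprocess -> differential replicate; returns the
    recovered group coefficient for the planted effect."""
    subj = synthetic.generate_subjects(synthetic.CohortConfig(seed=seed))
    assay = synthetic.generate_raw_assay(
        subj, [synthetic.EffectSpec(metabolite, group, effect)], seed=seed + 10_000)
    proc = preprocessing.preprocess_assay(assay, subj)
    groups = subj.set_index("subject_id")["group"].reindex(proc.z.index)
    dopa = preprocessing.derive_dopa_indicators(proc.z["DOPA"], groups)
    covs = regression.prepare_covariates(subj, dopa.reset_index(drop=True))
    table = regression.run_differential(proc.z[[metabolite]], covs)
    return float(table.query("term == @group")["beta"].iloc[0])


def effect_recovery(n_reps: int = 50, seed: int = 0,
                    effect: float = -0.73) -> dict:
    """Recovery of a planted metabolite group effect through the complete
    pipeline at the 136-subject cohort scale."""
    betas = np.array([_pipeline_beta(seed * 1000 + r, effect)
                      for r in range(n_reps)])
    return {"planted": effect, "mean_beta": float(betas.mean()),
            "bias": float(betas.mean() - effect), "sd": float(betas.std(ddof=1)),
            "n": n_reps}


def variance_ratio_recovery(n_reps: int = 50, seed: int = 0, n: int = 2000,
                            true_ratio_sd: float = 2.0) -> dict:
    """Recovery of a planted group-B/group-A residual-SD ratio of 2 (variance
    ratio 4) by the heteroscedastic ML fit; reports the fraction of
    replicates with the SD-ratio estimate inside [1.8, 2.2]."""
    rng = np.random.default_rng(seed)
    inside = 0
    est = []
    for _ in range(n_reps):
        g = np.repeat(["A", "B"], n // 2)
        x = rng.normal(size=n)
        sd = np.where(g == "B", true_ratio_sd, 1.0)
        y = 0.5 * x + rng.normal(size=n) * sd
        X = pd.DataFrame({"const": 1.0, "x": x, "gB": (g == "B").astype(float)})
        fit = regression.fit_group_hetero_lm(y, X, g)
        ratio = np.sqrt(fit.variance_multipliers["B"])
        est.append(ratio)
        inside += 1.8 <= ratio <= 2.2
    return {"fraction_inside": inside / n_reps, "mean_ratio": float(np.mean(est)),
            "n": n_reps}


def boxcox_lambda_coverage(n_reps: int = 100, seed: int = 0, n: int = 500) -> dict:
    """Fraction of log-normal samples (true lambda 0) whose estimated Box-Cox
    exponent lands inside [-0.15, 0.15], plus the Gaussian-shaped control
    (true lambda 1)."""
    rng = np.random.default_rng(seed)
    inside0 = 0
    lam1 = []
    for _ in range(n_reps):
        lam = preprocessing.estimate_boxcox_lambda(np.exp(rng.normal(0, 0.5, n)))
        inside0 += abs(lam) <= 0.15
        lam1.append(preprocessing.estimate_boxcox_lambda(rng.normal(20, 2, n)))
    return {"fraction_lognormal_inside": inside0 / n_reps,
            "mean_lambda_gaussian": float(np.mean(lam1)), "n": n_reps}


def inheritance_selection_rate(n_reps: int = 100, seed: int = 0, n: int = 150,
                               maf: float = 0.3, effect: float = 1.5) -> dict:
    """Fraction of replicates in which BIC selection recovers the generating
    (recessive) inheritance model at a 1.5-SD homozygote effect."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        g = rng.binomial(2, maf, n).astype(float)
        covs = pd.DataFrame({"age": rng.normal(80, 8, n)})
        y = effect * (g == 2) + 0.01 * covs["age"] + rng.normal(size=n)
        fit = snp.choose_inheritance_model(g, y, covs)
        hits += fit.model == "recessive"
    return {"recessive_rate": hits / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def type_i_error(n_seeds: int = 100, seed: int = 0, alpha: float = 0.05) -> dict:
    """Differential-pipeline false-positive rate on null synthetic cohorts
    (no planted effects): fraction of per-metabolite group-term tests with
    p < alpha across seeds."""
    hits = 0
    total = 0
    for s in range(n_seeds):
        subj = synthetic.generate_subjects(synthetic.CohortConfig(seed=seed + s))
        assay = synthetic.generate_raw_assay(subj, [], seed=seed + s + 50_000)
        proc = preprocessing.preprocess_assay(assay, subj)
        groups = subj.set_index("subject_id")["group"].reindex(proc.z.index)
        dopa = preprocessing.derive_dopa_indicators(proc.z["DOPA"], groups)
        covs = regression.prepare_covariates(subj, dopa.reset_index(drop=True))
        mets = [m for m in proc.z.columns if m != "DOPA"]
        table = regression.run_differential(proc.z[mets], covs)
        hits += int((table["p"] < alpha).sum())
        total += len(table)
    return {"rate": hits / total, "n_tests": total, "n_seeds": n_seeds}


def null_score_delta(n_seeds: int = 100, seed: int = 0) -> dict:
    """Composite-score percent differences from controls under the null (no
    planted genotype or metabolite structure): mean Delta% across seeds,
    expected to centre on zero."""
    deltas = []
    sizes = {"HC-CN": 36, "PD-D": 32}
    sets = scores.RiskSets(
        snp_risk=[("s1", "dominant"), ("s2", "recessive"), ("s3", "additive")],
        snp_protect=[("s4", "dominant")], vitamin_risk=["m1", "m2"])
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        subj = synthetic.generate_subjects(
            synthetic.CohortConfig(group_sizes=sizes, seed=seed + s))
        G = pd.DataFrame({f"s{i}": rng.binomial(2, 0.3, len(subj)).astype(float)
                          for i in range(1, 5)},
                         index=pd.Index(subj["subject_id"], name="subject_id"))
        z = pd.DataFrame(rng.normal(size=(len(subj), 2)), columns=["m1", "m2"],
                         index=G.index)
        groups = subj.set_index("subject_id")["group"]
        _, cmp_table = scores.score_table(G, z, sets, groups)
        deltas.extend(cmp_table.loc[cmp_table["score"] != "vitamin_risk",
                                    "delta_pct"].tolist())
    return {"mean_delta_pct": float(np.mean(deltas)), "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# LD and GP behaviour
# ---------------------------------------------------------------------------

def ld_repulsion_dprime(seed: int = 0, n: int = 500) -> dict:
    """D' estimated from a repulsion-phase pair simulated with no
    double-mutant haplotype (the mutual-exclusivity pattern)."""
    subj = synthetic.generate_subjects(
        synthetic.CohortConfig(group_sizes={"HC-CN": n}, seed=seed))
    specs = [synthetic.SNPSpec("s1", 0.30), synthetic.SNPSpec("s2", 0.25)]
    G = synthetic.generate_genotypes(
        subj, specs, [synthetic.LDSpec(("s1", "s2"), 1.0, "repulsion")],
        seed=seed + 1)
    r = snp.ld_stats(G["s1"], G["s2"])
    return {"dprime": r.Dprime, "p": r.p, "n": n}


def gp_penalty_linearity() -> dict:
    """Fitness drop from adding a redundant operand: exactly the 0.05-per-
    operand parsimony penalty when predictions are unchanged."""
    rng = np.random.default_rng(0)
    n = 60
    feats = pd.DataFrame({"m1": rng.normal(size=n),
                          "snpA": rng.binomial(2, 0.3, n).astype(float)})
    labels = (feats["snpA"] >= 1).to_numpy()
    pool = gp.enumerate_operands(["m1"], ["snpA"])
    V = gp.operand_matrix(pool, feats)
    leaf = ("L", pool.index(gp.Operand("snp_threshold", "snpA", 1.0)))
    base = gp.fitness(leaf, V, labels)
    redundant = ("OR", leaf, leaf)  # identical predictions, one more operand
    return {"fitness_drop": base - gp.fitness(redundant, V, labels),
            "base_fitness": base}


def gp_rule_recovery(n_seeds: int = 10, seed: int = 0, *, population: int = 5000,
                     generations: int = 30, runs: int = 5, n: int = 100) -> dict:
    """Recovery of a planted noiseless two-SNP Boolean rule: fraction of
    seeds whose best tree reaches per-class accuracies >= 0.95."""
    successes = 0
    accs = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 100 + s)
        feats = pd.DataFrame({
            "m1": rng.normal(size=n), "m2": rng.normal(size=n),
            "snpA": rng.binomial(2, 0.3, n).astype(float),
            "snpB": rng.binomial(2, 0.3, n).astype(float),
        })
        labels = synthetic.plant_classification_rule(
            feats, "(snpA == 0) & (snpB == 0)", 0.0)
        if labels.all() or not labels.any():
            labels.iloc[0] = not labels.iloc[0]
        cfg = gp.GPConfig(population_size=population, generations=generations,
                          runs=runs, seed=seed + s)
        res = gp.evolve(feats, labels.to_numpy(), cfg,
                        metabolites=["m1", "m2"], snps=["snpA", "snpB"])
        accs.append(res.class_accuracies)
        successes += min(res.class_accuracies) >= 0.95
    return {"success_fraction": successes / n_seeds,
            "mean_min_accuracy": float(np.mean([min(a) for a in accs])),
            "n_seeds": n_seeds}


def scenario_run(seed: int = 0) -> dict:
    """One full default-scenario pipeline run (study-structured effects, SNP
    panel with LD pair, scaled-down GP budget); returns headline outputs."""
    from neuro1c import pipeline
    import tempfile
    with tempfile.TemporaryDirectory() as td:
        cfg = pipeline.RunConfig(out_dir=td, seed=seed)
        pipeline.run_all(cfg)
        import json
        from pathlib import Path
        report = json.loads((Path(td) / "report.json").read_text())
    return report
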