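"""Composite genetic / metabolic burden scores.

Three unweighted counts per subject aggregate the Hcy/betaine association
results: (A) SNP risk score — polymorphisms associated with elevated Hcy or
decreased betaine, counted under each SNP's chosen inheritance model;
(B) SNP protection score — the converse direction; (C) B-vitamin risk
score — vitamins positively tied to one-carbon health (negatively associated
with Hcy or positively with betaine) whose level falls below the estimated
control 5th percentile (z < -1.64).  Groups are compared with controls by
percent mean difference and Wilcoxon-Mann-Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neuro1c.snp import wmw_group_test

#: Inverse standard-normal CDF at 0.05 (full precision; displayed as -1.64):
#: the "deficient vitamin" z threshold.
VITAMIN_Z_THRESHOLD = -1.6449


@dataclass
class RiskSets:
    """Membership of the three composite scores.

    ``snp_risk`` / ``snp_protect`` hold (snp_id, inheritance_model) pairs;
    ``vitamin_risk`` holds metabolite names.  A SNP never appears in both
    SNP sets.
    """

    snp_risk: list = field(default_factory=list)
    snp_protect: list = field(default_factory=list)
    vitamin_risk: list = field(default_factory=list)
    z_threshold: float = VITAMIN_Z_THRESHOLD


def build_risk_sets(
    snp_assoc: pd.DataFrame,
    vitamin_assoc: pd.DataFrame,
    *,
    snp_q_threshold: float = 0.10,
    vitamin_fdr_threshold: float = 0.05,
) -> RiskSets:
    """Derive the score membership sets from association tables.

    ``snp_assoc`` rows need columns snp, model, direction, q (concatenated
    Hcy and betaine scans are fine — a SNP significant in both with a
    consistent direction is counted once; conflicting directions drop the
    SNP with a warning).  ``vitamin_assoc`` rows need feature, beta, fdr and
    a ``response`` column naming Hcy or betaine; membership requires a
    significant Hcy-negative or betaine-positive coefficient.
    """
    risk: dict = {}
    protect: dict = {}
    if len(snp_assoc):
        sig = snp_assoc[snp_assoc["q"] <= snp_q_threshold]
        for _, row in sig.iterrows():
            bucket = risk if row["direction"] == "risk" else protect
            bucket.setdefault(row["snp"], row["model"])
        clash = set(risk) & set(protect)
        if clash:
            warnings.warn(f"SNPs with conflicting directions dropped: {sorted(clash)}")
            for s in clash:
                risk.pop(s)
                protect.pop(s)
    else:
        warnings.warn("empty SNP association table; SNP sets empty")

    vitamins: list = []
    if len(vitamin_assoc):
        sig = vitamin_assoc[vitamin_assoc["fdr"] <= vitamin_fdr_threshold]
        for _, row in sig.iterrows():
            good = ((row["response"] == "Hcy" and row["beta"] < 0)
                    or (row["response"] == "betaine" and row["beta"] > 0))
            if good and row["feature"] not in vitamins:
                vitamins.append(row["feature"])
    else:
        warnings.warn("empty vitamin association table; vitamin set empty")

    return RiskSets(snp_risk=sorted(risk.items()),
                    snp_protect=sorted(protect.items()),
                    vitamin_risk=vitamins)


def _criterion_met(g: float, model: str, mode: str) -> float:
    if not np.isfinite(g):
        return np.nan
    if model == "dominant":
        return float(g >= 1)
    if model == "recessive":
        return float(g == 2)
    # additive: carrier mode counts any alternate allele once; allele-count
    # mode contributes the allele count itself
    return float(g >= 1) if mode == "carrier" else float(g)


def snp_score(genotypes: pd.DataFrame, snp_set, *,
              additive_mode: str = "carrier") -> pd.Series:
    """Per-subject count of set SNPs whose model criterion the subject meets.

    Missing genotypes: the score is computed over the observed set members
    and rescaled to the full set size (rounded half-up is NOT applied — the
    rescaled value stays fractional so ranks are preserved)."""
    if additive_mode not in ("carrier", "allele_count"):
        raise ValueError("additive_mode must be 'carrier' or 'allele_count'")
    if not snp_set:
        return pd.Series(0.0, index=genotypes.index, name="score")
    contrib = pd.DataFrame(index=genotypes.index)
    for snp, model in snp_set:
        g = genotypes[snp]
        contrib[snp] = [
            _criterion_met(v, model, additive_mode) for v in g.to_numpy(float)]
    observed = contrib.notna().sum(axis=1)
    raw = contrib.sum(axis=1, skipna=True)
    scale = len(snp_set) / observed.replace(0, np.nan)
    return (raw * scale).fillna(0.0).rename("score")


def vitamin_risk_score(z: pd.DataFrame, vitamin_set,
                       threshold: float = VITAMIN_Z_THRESHOLD) -> pd.Series:
    """Per-subject count of set vitamins with z below the control 5th
    percentile threshold."""
    if not vitamin_set:
        return pd.Series(0.0, index=z.index, name="score")
    below = z[list(vitamin_set)] < threshold
    return below.sum(axis=1).astype(float).rename("score")


def compare_to_controls(scores: pd.Series, groups: pd.Series,
                        control_group: str = "HC-CN") -> pd.DataFrame:
    """Per-group percent mean difference from controls and two-sided WMW p.

    Delta% = 100 (mean_group - mean_controls) / mean_controls; when the
    control mean is zero the absolute difference is reported instead and
    flagged.
    """
    groups = groups.reindex(scores.index)
    ctrl = scores[groups == control_group]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_group!r} absent")
    ctrl_mean = float(ctrl.mean())
    rows = []
    for g in groups.unique():
        if g == control_group:
            continue
        vals = scores[groups == g]
        diff = float(vals.mean()) - ctrl_mean
        if ctrl_mean != 0:
            delta, absolute = 100.0 * diff / ctrl_mean, False
        else:
            delta, absolute = diff, True
        rows.append({"group": g, "n": len(vals), "mean": float(vals.mean()),
                     "control_mean": ctrl_mean, "delta_pct": delta,
                     "absolute_diff": absolute,
                     "p": wmw_group_test(vals.to_numpy(), ctrl.to_numpy())})
    return pd.DataFrame(rows)


def score_table(genotypes: pd.DataFrame, z: pd.DataFrame, sets: RiskSets,
                groups: pd.Series, *, control_group: str = "HC-CN",
                additive_mode: str = "carrier") -> tuple[pd.DataFrame, pd.DataFrame]:
    """All three scores per subject plus the per-group comparison summary."""
    idx = genotypes.index.intersection(z.index)
    table = pd.DataFrame({
        "snp_risk": snp_score(genotypes.loc[idx], sets.snp_risk,
                              additive_mode=additive_mode),
        "snp_protection": snp_score(genotypes.loc[idx], sets.snp_protect,
                                    additive_mode=additive_mode),
        "vitamin_risk": vitamin_risk_score(z.loc[idx], sets.vitamin_risk,
                                           sets.z_threshold),
    })
    comparisons = []
    for col in table.columns:
        cmp = compare_to_controls(table[col], groups, control_group)
        cmp.insert(0, "score", col)
        comparisons.append(cmp)
    return table, pd.concat(comparisons, ignore_index=True)
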