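"""Synthetic cohort, assay-plate, and genotype generators.

Every downstream stage of the pipeline is exercised on data from this module,
so the generators reproduce the statistical structure the analysis assumes:
log-normal metabolite concentrations with group effects expressed in
control-SD units, plate batch offsets, blank/QC/calibrator wells on a known
quadratic response, Hardy-Weinberg genotypes with optional two-locus linkage
disequilibrium planted by explicit haplotype-pool sampling, an acutely
levodopa-exposed subset of PD subjects, and an optional planted Boolean
classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("HC-CN", "PD-CN", "PD-MCI", "PD-D", "AD-D")

#: Default cohort composition: 136 frontal-cortex subjects across the five
#: diagnostic groups (healthy controls; PD cognitively normal / mild cognitive
#: impairment / dementia; AD dementia).
DEFAULT_GROUP_SIZES = {
    "HC-CN": 36,
    "PD-CN": 14,
    "PD-MCI": 19,
    "PD-D": 32,
    "AD-D": 35,
}

#: Per-group covariate distributions: age and education in years, BMI in
#: kg/m^2, post-mortem collection interval (PMI) in hours, freezer storage in
#: years; comorbidity prevalences as probabilities.
DEFAULT_COVARIATE_PARAMS = {
    "HC-CN": dict(age=(82, 10), male=0.61, education=(14, 3), bmi=(25, 5),
                  pmi=(3.2, 1.0), storage=(12, 4),
                  hyperlipidemia=0.36, diabetes=0.33, renal=0.14,
                  hypothyroid=0.25, supplementation=0.30),
    "PD-CN": dict(age=(85, 6), male=0.57, education=(16, 3), bmi=(22, 4),
                  pmi=(3.3, 0.9), storage=(10, 4),
                  hyperlipidemia=0.50, diabetes=0.07, renal=0.21,
                  hypothyroid=0.21, supplementation=0.30),
    "PD-MCI": dict(age=(82, 6), male=0.74, education=(14, 3), bmi=(25, 8),
                   pmi=(3.4, 1.2), storage=(8, 4),
                   hyperlipidemia=0.47, diabetes=0.16, renal=0.11,
                   hypothyroid=0.26, supplementation=0.30),
    "PD-D": dict(age=(80, 5), male=0.75, education=(16, 3), bmi=(27, 9),
                 pmi=(3.4, 0.9), storage=(10, 4),
                 hyperlipidemia=0.34, diabetes=0.25, renal=0.16,
                 hypothyroid=0.16, supplementation=0.30),
    "AD-D": dict(age=(81, 9), male=0.57, education=(15, 2), bmi=(24, 4),
                 pmi=(3.4, 0.8), storage=(9, 2),
                 hyperlipidemia=0.57, diabetes=0.17, renal=0.06,
                 hypothyroid=0.09, supplementation=0.30),
}

#: Targeted one-carbon / B-vitamin panel measured in the simulated assay.
DEFAULT_PANEL = (
    "Hcy", "betaine", "biotin", "PLP", "ThMP", "ThPP", "thiamine",
    "riboflavin", "niacin", "NAM", "PA", "MeCbl", "MMA", "THF", "MTHF", "DOPA",
)

COMORBIDITIES = ("hyperlipidemia", "diabetes", "renal", "hypothyroid")


class ConfigurationError(ValueError):
    """Invalid simulation configuration (unknown labels, unreachable targets)."""


@dataclass
class CohortConfig:
    """Cohort composition and covariate distributions.

    ``levodopa_fraction`` is the fraction of PD subjects with acute levodopa
    exposure at death (elevated tissue DOPA).  Identical seeds produce
    byte-identical cohorts.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    covariate_params: dict = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_COVARIATE_PARAMS.items()}
    )
    levodopa_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in self.covariate_params:
                raise ConfigurationError(f"unknown group label {g!r}")
            if n < 0:
                raise ConfigurationError(f"negative count for group {g!r}")
        if not 0.0 <= self.levodopa_fraction <= 1.0:
            raise ConfigurationError("levodopa_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect on one metabolite, in control-SD units.

    When ``levodopa_only`` is set the effect applies only to subjects of the
    group with acute levodopa exposure (the DOPA-interaction pattern).
    """

    metabolite: str
    group: str
    effect: float
    levodopa_only: bool = False


@dataclass(frozen=True)
class CouplingSpec:
    """A planted within-subject association between two metabolites.

    The response's log-value gains ``slope`` x the predictor's standardised
    biological deviation, so the post-pipeline regression of response on
    predictor (both in control-SD units, groups adjusted) recovers a
    coefficient near ``slope``.
    """

    response: str
    predictor: str
    slope: float


@dataclass(frozen=True)
class SNPSpec:
    """A simulated biallelic SNP.

    Genotypes are sampled under Hardy-Weinberg equilibrium at ``maf`` unless
    ``group_odds`` rescales the allele odds per group.  ``effect_on`` plants
    an effect (metabolite name, control-SD units per coding unit) routed
    through the declared inheritance model.
    """

    snp_id: str
    maf: float
    inheritance: str = "additive"
    effect_on: tuple | None = None  # (metabolite, effect_sd)
    group_odds: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ConfigurationError(f"{self.snp_id}: maf must lie in (0, 0.5]")
        if self.inheritance not in ("dominant", "recessive", "additive"):
            raise ConfigurationError(f"{self.snp_id}: unknown inheritance model")


@dataclass(frozen=True)
class LDSpec:
    """Two-locus linkage-disequilibrium target.

    ``phase='coupling'`` places minor alleles on the same haplotype
    (positive D), ``'repulsion'`` on opposite haplotypes (negative D); at
    ``target_dprime=1`` in repulsion phase the double-mutant haplotype has
    frequency zero, i.e. the two mutations are mutually exclusive.
    """

    snp_pair: tuple
    target_dprime: float = 1.0
    phase: str = "repulsion"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_dprime <= 1.0:
            raise ConfigurationError("target_dprime must lie in [0, 1]")
        if self.phase not in ("coupling", "repulsion"):
            raise ConfigurationError("phase must be 'coupling' or 'repulsion'")


def _truncated_normal(rng, mean, sd, size, lower, upper=np.inf):
    """Normal draws re-drawn into [lower, upper] (simple rejection)."""
    x = rng.normal(mean, sd, size)
    bad = (x < lower) | (x > upper)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lower) | (x > upper)
    return x


def generate_subjects(config: CohortConfig) -> pd.DataFrame:
    """Generate the subject table: one row per subject with group label,
    demographics, comorbidity flags, supplementation flag, tissue-handling
    covariates and the acute-levodopa exposure indicator."""
    rng = np.random.default_rng(config.seed)
    rows = []
    idx = 0
    for group in config.group_sizes:
        n = config.group_sizes[group]
        p = config.covariate_params[group]
        if n == 0:
            continue
        age = _truncated_normal(rng, *p["age"], n, 40.0)
        male = rng.random(n) < p["male"]
        edu = _truncated_normal(rng, *p["education"], n, 6.0)
        bmi = _truncated_normal(rng, *p["bmi"], n, 14.0)
        pmi = _truncated_normal(rng, *p["pmi"], n, 0.5)
        storage = _truncated_normal(rng, *p["storage"], n, 0.5)
        comorb = {c: rng.random(n) < p[c] for c in COMORBIDITIES}
        suppl = rng.random(n) < p["supplementation"]
        is_pd = group.startswith("PD")
        levodopa = (rng.random(n) < config.levodopa_fraction) if is_pd else np.zeros(n, bool)
        for i in range(n):
            rows.append({
                "subject_id": f"S{idx:04d}",
                "group": group,
                "sex": "M" if male[i] else "F",
                "age": round(age[i], 1),
                "education": round(edu[i], 1),
                "bmi": round(bmi[i], 1),
                "pmi_hours": round(pmi[i], 2),
                "storage_years": round(storage[i], 2),
                **{c: int(comorb[c][i]) for c in COMORBIDITIES},
                "supplementation": int(suppl[i]),
                "levodopa_acute": int(levodopa[i]),
            })
            idx += 1
    cols = ["subject_id", "group", "sex", "age", "education", "bmi",
            "pmi_hours", "storage_years", *COMORBIDITIES,
            "supplementation", "levodopa_acute"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Raw assay plates
# ---------------------------------------------------------------------------

#: Quadratic instrument response signal = a + b*c + c2*c^2 used for every
#: metabolite; a is the blank-level background.
RESPONSE_COEF = (50.0, 100.0, 0.5)
CALIBRATOR_LEVELS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
LOG_CONC_MEAN = 1.6  # log-scale location of a typical metabolite
BLANK_NOISE_SD = 2.0
#: Log-DOPA elevation (in units of the biological log-SD) for acutely
#: levodopa-exposed PD subjects; far above the control 95th percentile.
DOPA_ELEVATION_SD = 4.0


def assign_plates(subjects: pd.DataFrame, n_plates: int = 2, *, stratify: bool = True,
                  seed: int = 0) -> pd.Series:
    """Assign each subject to a plate; by default stratified by group so
    every plate carries a balanced group composition."""
    rng = np.random.default_rng(seed)
    plate = pd.Series(index=subjects.index, dtype=int)
    if stratify:
        # round-robin over a shuffled within-group order: near-equal fill per group
        for _, block in subjects.groupby("group", sort=False):
            order = rng.permutation(len(block))
            plate.loc[block.index] = [i % n_plates for i in order]
    else:
        order = rng.permutation(len(subjects))
        plate.loc[subjects.index] = [i % n_plates for i in order]
    return plate.astype(int)


def generate_raw_assay(
    subjects: pd.DataFrame,
    effects: Sequence[EffectSpec] = (),
    *,
    panel: Sequence[str] = DEFAULT_PANEL,
    couplings: Sequence[CouplingSpec] = (),
    n_plates: int = 2,
    stratify: bool = True,
    noise_sd: float = 0.25,
    plate_offset_sd: float = 0.3,
    plate_offsets: np.ndarray | None = None,
    blanks_per_plate: int = 3,
    qc_per_plate: int = 3,
    subject_offsets: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-plate raw peak areas for samples, blanks, QC replicates
    and calibrators.

    Sample log-concentration = base + (planted effect in control-SD units) x
    noise_sd + plate offset + N(0, noise_sd); the instrument maps
    concentration to signal through a known quadratic response, so the
    preprocessing stage can calibrate back.  ``subject_offsets`` (subjects x
    metabolites, control-SD units) plants per-subject effects such as SNP
    influences.  Returns a long table with columns plate, well_type,
    subject_id, metabolite, signal, calib_conc.
    """
    panel = list(panel)
    for e in effects:
        if e.metabolite not in panel:
            raise ConfigurationError(f"effect on unknown metabolite {e.metabolite!r}")
        if e.group not in set(subjects["group"]):
            raise ConfigurationError(f"effect on unknown group {e.group!r}")
    rng = np.random.default_rng(seed)
    plates = assign_plates(subjects, n_plates, stratify=stratify, seed=seed + 1)
    if plate_offsets is None:
        plate_offsets = rng.normal(0.0, plate_offset_sd, (n_plates, len(panel)))
    plate_offsets = np.asarray(plate_offsets, float)

    for cp in couplings:
        if cp.response not in panel or cp.predictor not in panel:
            raise ConfigurationError(
                f"coupling references metabolite outside the panel: {cp}")

    a, b, c2 = RESPONSE_COEF
    rows = []
    n = len(subjects)
    # biological deviations in control-SD units: planted group effects +
    # per-subject offsets + unit noise; couplings then mix in the
    # predictor's deviation before scaling to the log-concentration scale
    dev = {}
    for met in panel:
        d = np.zeros(n)
        for e in effects:
            if e.metabolite != met:
                continue
            mask = (subjects["group"] == e.group).to_numpy()
            if e.levodopa_only:
                mask &= subjects["levodopa_acute"].to_numpy().astype(bool)
            d = d + np.where(mask, e.effect, 0.0)
        if met == "DOPA":
            exposed = subjects["levodopa_acute"].to_numpy().astype(bool)
            d = d + np.where(exposed, DOPA_ELEVATION_SD, 0.0)
        if subject_offsets is not None and met in subject_offsets.columns:
            off = subject_offsets[met].reindex(subjects["subject_id"]).fillna(0.0)
            d = d + off.to_numpy()
        dev[met] = d
    eps = {met: rng.normal(0.0, 1.0, n) for met in panel}
    # couplings mix predictor noise into the response at the planted slope
    # while keeping the response's biological variance at 1, so the
    # group-adjusted regression coefficient of response on predictor (both
    # control-standardised) centres on the slope itself
    slopes: dict[str, list[CouplingSpec]] = {}
    for cp in couplings:
        slopes.setdefault(cp.response, []).append(cp)
    coupled = {}
    for met in panel:
        cps = slopes.get(met, [])
        own = np.sqrt(max(1.0 - sum(c.slope**2 for c in cps), 0.05))
        e = own * eps[met]
        for c in cps:
            e = e + c.slope * eps[c.predictor]
        coupled[met] = dev[met] + e
    for j, met in enumerate(panel):
        logc = (LOG_CONC_MEAN + noise_sd * coupled[met]
                + plate_offsets[plates.to_numpy(), j])
        conc = np.exp(logc)
        signal = a + b * conc + c2 * conc**2
        for i, sid in enumerate(subjects["subject_id"]):
            rows.append((int(plates.iloc[i]), "sample", sid, met,
                         signal[i], np.nan))
        for p in range(n_plates):
            for _ in range(blanks_per_plate):
                rows.append((p, "blank", "", met,
                             a + rng.normal(0.0, BLANK_NOISE_SD), np.nan))
            qc_conc = np.exp(LOG_CONC_MEAN + plate_offsets[p, j]
                             + rng.normal(0.0, 0.02, qc_per_plate))
            for q in qc_conc:
                rows.append((p, "qc", "", met, a + b * q + c2 * q**2, np.nan))
            for level in CALIBRATOR_LEVELS:
                rows.append((p, "calibrator", "", met,
                             a + b * level + c2 * level**2, level))
    return pd.DataFrame(rows, columns=["plate", "well_type", "subject_id",
                                       "metabolite", "signal", "calib_conc"])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _haplotype_frequencies(maf1: float, maf2: float, dprime: float,
                           phase: str) -> np.ndarray:
    """Four haplotype frequencies (ab, aB, Ab, AB; capital = minor allele)
    solved from the two MAFs and a target D' with the requested phase."""
    p, q = maf1, maf2
    if phase == "coupling":
        dmax = min(p * (1 - q), (1 - p) * q)
        d = dprime * dmax
    else:
        dmax = min(p * q, (1 - p) * (1 - q))
        d = -dprime * dmax
    f_ab = (1 - p) * (1 - q) + d
    f_aB = (1 - p) * q - d
    f_Ab = p * (1 - q) - d
    f_AB = p * q + d
    freqs = np.array([f_ab, f_aB, f_Ab, f_AB])
    if (freqs < -1e-12).any():
        raise ConfigurationError(
            f"LD target D'={dprime} ({phase}) unreachable at MAFs {p}, {q}")
    return np.clip(freqs, 0.0, 1.0)


def _group_maf(spec: SNPSpec, group: str) -> float:
    if spec.group_odds and group in spec.group_odds:
        odds = spec.maf / (1 - spec.maf) * spec.group_odds[group]
        return odds / (1 + odds)
    return spec.maf


def generate_genotypes(
    subjects: pd.DataFrame,
    snp_specs: Sequence[SNPSpec],
    ld_specs: Sequence[LDSpec] = (),
    *,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate subjects x SNPs minor-allele counts (0/1/2, NaN = missing).

    Independent SNPs follow Hardy-Weinberg sampling at the (possibly
    group-adjusted) MAF; SNP pairs named by an ``LDSpec`` are drawn jointly
    from an explicit four-haplotype pool solved for the target D'.
    """
    spec_by_id = {s.snp_id: s for s in snp_specs}
    if len(spec_by_id) != len(snp_specs):
        raise ConfigurationError("duplicate snp_id in specs")
    in_ld: set[str] = set()
    for ld in ld_specs:
        for sid in ld.snp_pair:
            if sid not in spec_by_id:
                raise ConfigurationError(f"LD spec names undeclared SNP {sid!r}")
            if sid in in_ld:
                raise ConfigurationError(f"SNP {sid!r} appears in two LD specs")
            in_ld.add(sid)
        if spec_by_id[ld.snp_pair[0]].group_odds or spec_by_id[ld.snp_pair[1]].group_odds:
            raise ConfigurationError("group_odds unsupported for SNPs in LD specs")

    rng = np.random.default_rng(seed)
    n = len(subjects)
    G = pd.DataFrame(index=pd.Index(subjects["subject_id"], name="subject_id"))

    for ld in ld_specs:
        s1, s2 = (spec_by_id[sid] for sid in ld.snp_pair)
        freqs = _haplotype_frequencies(s1.maf, s2.maf, ld.target_dprime, ld.phase)
        # haplotypes coded (allele1, allele2): 0=ab 1=aB 2=Ab 3=AB
        hap_alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        h1 = rng.choice(4, n, p=freqs)
        h2 = rng.choice(4, n, p=freqs)
        G[s1.snp_id] = hap_alleles[h1, 0] + hap_alleles[h2, 0]
        G[s2.snp_id] = hap_alleles[h1, 1] + hap_alleles[h2, 1]

    groups = subjects["group"].to_numpy()
    for spec in snp_specs:
        if spec.snp_id in in_ld:
            continue
        if spec.group_odds:
            maf = np.array([_group_maf(spec, g) for g in groups])
        else:
            maf = np.full(n, spec.maf)
        G[spec.snp_id] = rng.binomial(1, maf) + rng.binomial(1, maf)

    G = G[[s.snp_id for s in snp_specs]].astype(float)
    if missing_rate > 0:
        mask = rng.random(G.shape) < missing_rate
        G = G.mask(mask)
    return G


def snp_effect_offsets(genotypes: pd.DataFrame,
                       snp_specs: Sequence[SNPSpec]) -> pd.DataFrame:
    """Per-subject metabolite offsets (control-SD units) implied by the
    ``effect_on`` fields of the SNP specs, routed through each SNP's
    inheritance model (dominant: carrier indicator, recessive: homozygote
    indicator, additive: allele count)."""
    out = pd.DataFrame(index=genotypes.index)
    for spec in snp_specs:
        if spec.effect_on is None:
            continue
        met, eff = spec.effect_on
        g = genotypes[spec.snp_id].fillna(0.0)
        if spec.inheritance == "dominant":
            coding = (g >= 1).astype(float)
        elif spec.inheritance == "recessive":
            coding = (g == 2).astype(float)
        else:
            coding = g
        out[met] = out.get(met, pd.Series(0.0, index=out.index)) + eff * coding
    return out


def mask_mcar(table: pd.DataFrame, column: str, rate: float, *,
              seed: int = 0) -> pd.DataFrame:
    """Return a copy with entries of ``column`` set missing completely at
    random at the given rate (exercises the downstream imputation and
    filtering paths)."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("missing rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    mask = rng.random(len(out)) < rate
    out.loc[mask, column] = np.nan
    return out


def plant_classification_rule(
    features: pd.DataFrame,
    rule: str | Callable[[pd.DataFrame], np.ndarray],
    noise_rate: float = 0.0,
    *,
    seed: int = 0,
) -> pd.Series:
    """Evaluate a Boolean rule over a feature table and flip each label with
    probability ``noise_rate``.  String rules use ``DataFrame.eval`` syntax,
    e.g. ``"(snpA == 0) & (snpB == 0)"``."""
    if callable(rule):
        labels = np.asarray(rule(features), bool)
    else:
        try:
            labels = features.eval(rule).to_numpy().astype(bool)
        except Exception as exc:  # pragma: no cover - message path
            raise ConfigurationError(f"malformed rule {rule!r}: {exc}") from exc
    if labels.shape != (len(features),):
        raise ConfigurationError("rule must yield one Boolean per row")
    if noise_rate:
        rng = np.random.default_rng(seed)
        labels = labels ^ (rng.random(len(labels)) < noise_rate)
    return pd.Series(labels, index=features.index, name="label")
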