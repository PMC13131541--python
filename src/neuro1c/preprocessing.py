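"""Raw plate signals -> analysis-ready control-standardised matrices.

The chain per metabolite is: quadratic calibration of peak areas, limit of
detection from blank wells (estimated 99.9th normal percentile of the blank
signal, mean + 3.09 SD, per plate), exclusion of metabolites consistently
below the LOD, group-respecting plate normalisation, Box-Cox transformation,
Tukey fencing (k = 3) of remote outliers, and standardisation against the
control group so regression coefficients read in control-SD units.  Helper
imputations (conditional-mean for covariates, half-minimum for undetected
peaks), the rare-SNP carrier filter, and the acute-levodopa indicators
derived from tissue DOPA also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

#: Inverse standard-normal CDF at 0.999, printed to two decimals: the blank
#: LOD multiplier.
LOD_MULTIPLIER = 3.09
#: Inverse standard-normal CDF at 0.95: acute-levodopa DOPA threshold.
NORMAL_Q95 = 1.6449


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Quadratic instrument response ``signal = a + b*conc + c*conc**2``.

    ``identity=True`` marks the uncalibrated fallback used when fewer than
    three distinct calibrator concentrations are available (relative-value
    mode); the inverse then returns the signal unchanged.
    """

    coefficients: tuple = (0.0, 1.0, 0.0)
    conc_range: tuple = (0.0, np.inf)
    residual_sd: float = 0.0
    identity: bool = False

    def signal(self, conc):
        a, b, c = self.coefficients
        conc = np.asarray(conc, float)
        return a + b * conc + c * conc**2

    def concentration(self, signal):
        """Invert signal -> concentration on the valid range (the root of
        the quadratic lying in ``conc_range``; single-valued there)."""
        if self.identity:
            return np.asarray(signal, float)
        a, b, c = self.coefficients
        y = np.asarray(signal, float)
        if abs(c) < 1e-300:
            return (y - a) / b
        disc = np.maximum(b * b - 4.0 * c * (a - y), 0.0)
        r1 = (-b + np.sqrt(disc)) / (2.0 * c)
        r2 = (-b - np.sqrt(disc)) / (2.0 * c)
        lo, hi = self.conc_range
        span = max(hi - lo, 1.0)
        in1 = (r1 >= lo - 0.5 * span) & (r1 <= hi + 0.5 * span)
        return np.where(in1, r1, r2)


def fit_calibration(points) -> CalibrationCurve:
    """Least-squares quadratic through (concentration, signal) calibrator
    points; falls back to the identity (relative mode) with a warning when
    fewer than three distinct concentrations are available."""
    pts = np.asarray(points, float)
    conc, sig = pts[:, 0], pts[:, 1]
    if len(np.unique(conc)) < 3:
        warnings.warn("fewer than 3 distinct calibrator levels; "
                      "falling back to uncalibrated relative values")
        return CalibrationCurve(identity=True)
    c2, b, a = np.polyfit(conc, sig, 2)
    resid = sig - (a + b * conc + c2 * conc**2)
    dof = max(len(conc) - 3, 1)
    return CalibrationCurve(
        coefficients=(a, b, c2),
        conc_range=(float(conc.min()), float(conc.max())),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


# ---------------------------------------------------------------------------
# Limit of detection
# ---------------------------------------------------------------------------

def compute_lod(blank_signals) -> float:
    """LOD = blank mean + 3.09 x blank SD (sample SD, ddof=1): the estimated
    99.9th percentile of the blank-signal distribution."""
    x = np.asarray(blank_signals, float)
    if len(x) < 2:
        raise PreprocessingError("need at least 2 blank wells for an LOD")
    return float(x.mean() + LOD_MULTIPLIER * x.std(ddof=1))


def flag_below_lod(signals: pd.DataFrame, plate_ids: pd.Series,
                   lods: pd.DataFrame) -> pd.Series:
    """Exclude a metabolite when the majority (> 50%) of its sample signals
    fall below their plate's LOD.

    ``signals``: subjects x metabolites raw signals; ``lods``: plates x
    metabolites LOD values.
    """
    flags = {}
    plate_arr = plate_ids.reindex(signals.index).to_numpy()
    for met in signals.columns:
        vals = signals[met].to_numpy(float)
        lod_per_sample = lods[met].reindex(plate_arr).to_numpy(float)
        ok = np.isfinite(vals)
        below = (vals < lod_per_sample) & ok
        flags[met] = bool(below.sum() > 0.5 * ok.sum())
    return pd.Series(flags, name="excluded_below_lod")


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------

def normalize_across_plates(values: pd.Series, plate_ids: pd.Series,
                            group_labels: pd.Series) -> pd.Series:
    """Remove plate-level location/scale differences while preserving group
    mean differences.

    Two-pass distribution alignment that respects group assignments:
    (1) subtract pooled per-group means, (2) per plate centre the residuals
    on their mean and rescale each plate's residual SD to the
    location-aligned pooled SD (moment-based alignment: remote outliers are
    handled downstream by the Tukey-fencing stage, and at typical plate
    sizes moment estimates track the batch effect with far less noise than
    robust ones), (3) add the group means back.  Plates with fewer than 3
    samples are left unadjusted with a warning; a single plate is returned
    unchanged.
    """
    series = values.astype(float)
    plates = plate_ids.reindex(series.index)
    if plates.nunique() <= 1:
        return series.copy()
    groups = group_labels.reindex(series.index)
    plate_codes, plate_levels = pd.factorize(plates)
    group_codes, _ = pd.factorize(groups)
    n_p, n_g = len(plate_levels), group_codes.max() + 1
    plate_n = np.bincount(plate_codes, minlength=n_p).astype(float)
    adjustable = plate_n >= 3
    for plate, ok in zip(plate_levels, adjustable):
        if not ok:
            warnings.warn(f"plate {plate!r} has < 3 samples; left unadjusted")
    group_n = np.bincount(group_codes, minlength=n_g).astype(float)

    # the alignment is iterated to a fixed point: forcing plate moments
    # shifts the group means slightly, so a single sweep is only
    # approximately idempotent.  ddof=0 moments keep the pooled scale an
    # exact fixed point of the rescaling.
    x = series.to_numpy(float).copy()
    for _ in range(200):
        gm = (np.bincount(group_codes, x, n_g) / group_n)[group_codes]
        r = x - gm
        pm = np.bincount(plate_codes, r, n_p) / plate_n
        centred = np.where(adjustable[plate_codes], r - pm[plate_codes], r)
        adj_mask = adjustable[plate_codes]
        pooled_sd = np.sqrt(np.mean(centred[adj_mask] ** 2)) if adj_mask.any() else 0.0
        psd = np.sqrt(np.bincount(plate_codes, centred**2, n_p) / plate_n)
        scale = np.where(adjustable & (psd > 0) & (pooled_sd > 0),
                         pooled_sd / np.maximum(psd, 1e-300), 1.0)
        out = centred * scale[plate_codes] + gm
        if np.max(np.abs(out - x)) < 1e-13 * max(1.0, np.max(np.abs(x))):
            x = out
            break
        x = out
    return pd.Series(x, index=series.index, name=series.name)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def estimate_boxcox_lambda(values, bounds=(-3.0, 3.0)) -> float:
    """Profile-likelihood Box-Cox exponent on a bounded interval.

    Maximises the Gaussian profile log-likelihood of the transformed sample
    over lambda in ``bounds`` (golden-section/Brent on the negated
    log-likelihood).  Values must be strictly positive.
    """
    x = np.asarray(values, float)
    if (x <= 0).any():
        raise PreprocessingError("Box-Cox requires strictly positive values")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x), bounds=bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def apply_boxcox(values, lam: float):
    """Box-Cox power transform ``(x**lam - 1)/lam`` (log at lam = 0)."""
    x = np.asarray(values, float)
    if (x <= 0).any():
        raise PreprocessingError("Box-Cox requires strictly positive values")
    return special.boxcox(x, lam)


def shift_positive(values):
    """Shift a sample to strict positivity for Box-Cox: adds ``1 - min`` when
    the minimum is non-positive. Returns (shifted, shift)."""
    x = np.asarray(values, float)
    m = np.nanmin(x)
    shift = 1.0 - m if m <= 0 else 0.0
    return x + shift, float(shift)


# ---------------------------------------------------------------------------
# Outliers / standardization / imputation
# ---------------------------------------------------------------------------

def tukey_winsorize(values, k: float = 3.0):
    """Clamp remote outliers to Tukey's fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation of order statistics at probabilities
    0.25/0.75.  Values inside the fences are untouched; the operation is
    idempotent and rank-preserving.
    """
    x = np.asarray(values, float)
    q1, q3 = np.nanquantile(x, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return np.clip(x, lo, hi)


def standardize_to_controls(values, control_mask):
    """z = (x - control mean) / control SD (ddof=1): effect sizes downstream
    read in units of one control-group standard deviation."""
    x = np.asarray(values, float)
    mask = np.asarray(control_mask, bool)
    ctrl = x[mask]
    ctrl = ctrl[np.isfinite(ctrl)]
    if len(ctrl) < 2:
        raise PreprocessingError("need >= 2 finite control values")
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise PreprocessingError("control SD is zero; cannot standardize")
    return (x - ctrl.mean()) / sd


def impute_conditional_mean(table: pd.DataFrame, column: str,
                            condition_cols=("group", "sex")) -> pd.DataFrame:
    """Fill missing covariate entries with the mean of their (group, sex)
    cell; empty cells fall back to the group mean, then the grand mean."""
    out = table.copy()
    x = out[column]
    if not x.isna().any():
        return out
    cell_mean = x.groupby([out[c] for c in condition_cols]).transform("mean")
    group_mean = x.groupby(out[condition_cols[0]]).transform("mean")
    fill = cell_mean
    if fill.isna().any():
        warnings.warn(f"empty ({'+'.join(condition_cols)}) cell for {column!r}; "
                      "falling back to group mean")
        fill = fill.fillna(group_mean).fillna(x.mean())
    out[column] = x.fillna(fill)
    return out


def half_min_interpolate(values, missing_mask=None):
    """Replace undetected measurements by half of the smallest detected
    value (the not-detected-peak convention)."""
    x = np.asarray(values, float).copy()
    mask = np.isnan(x) if missing_mask is None else np.asarray(missing_mask, bool)
    detected = x[~mask]
    detected = detected[np.isfinite(detected)]
    if len(detected) == 0:
        raise PreprocessingError("no detected values to interpolate from")
    x[mask] = detected.min() / 2.0
    return x


def filter_rare_snps(genotypes: pd.DataFrame, min_carriers: int = 5,
                     *, count: str = "carriers") -> pd.DataFrame:
    """Drop SNPs whose alternate allele is present in fewer than
    ``min_carriers`` samples.

    ``count='carriers'`` counts subjects with at least one alternate allele
    (default); ``count='alleles'`` counts alleles.
    """
    if count == "carriers":
        tally = (genotypes >= 1).sum(axis=0)
    elif count == "alleles":
        tally = genotypes.sum(axis=0)
    else:
        raise ValueError("count must be 'carriers' or 'alleles'")
    return genotypes.loc[:, tally >= min_carriers]


def derive_dopa_indicators(log_dopa: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Acute-levodopa indicators from tissue DOPA.

    A PD subject is levodopa-positive (L+) when its log-DOPA exceeds the
    estimated normal 95th percentile of controls (control mean +
    1.6449 x control SD).  The flag is routed into separate covariates for
    demented (PD-D) and non-demented (PD-MCI/PD-CN) PD; controls and AD are
    never flagged.
    """
    ctrl = log_dopa[groups == "HC-CN"]
    if len(ctrl) < 2:
        raise PreprocessingError("no controls available for the DOPA threshold")
    thr = ctrl.mean() + NORMAL_Q95 * ctrl.std(ddof=1)
    is_pd = groups.str.startswith("PD")
    above = (log_dopa > thr) & is_pd
    pd_d = (groups == "PD-D")
    out = pd.DataFrame(index=log_dopa.index)
    out["dopa_pdd"] = (above & pd_d).astype(int)
    out["dopa_pdnd"] = (above & ~pd_d).astype(int)
    return out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class ProcessedMatrix:
    """Subjects x metabolites control-standardised z-values plus per-
    metabolite transform metadata (Box-Cox lambda and shift, control
    mean/SD on the transformed scale, LODs, exclusion flags, Tukey
    adjustment counts)."""

    z: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def metabolites(self):
        return list(self.z.columns)


def preprocess_assay(
    assay: pd.DataFrame,
    subjects: pd.DataFrame,
    *,
    control_group: str = "HC-CN",
    tukey_k: float = 3.0,
    boxcox: bool = True,
) -> ProcessedMatrix:
    """Run the full preprocessing chain on a long-format raw assay table.

    Per metabolite: fit the per-plate quadratic calibration and map sample
    signals to concentrations; compute per-plate blank LODs and drop
    metabolites with a majority of samples below the LOD; interpolate
    undetected (non-finite) sample values at half the minimum detected
    concentration; normalise across plates respecting groups; Box-Cox;
    Tukey-winsorize (k=3); standardise against the control group.
    """
    samples = assay[assay["well_type"] == "sample"]
    signals = samples.pivot_table(index="subject_id", columns="metabolite",
                                  values="signal", aggfunc="mean")
    signals = signals.reindex(subjects["subject_id"])
    plate_of = (samples.drop_duplicates("subject_id")
                .set_index("subject_id")["plate"]
                .reindex(signals.index))
    groups = subjects.set_index("subject_id")["group"].reindex(signals.index)
    control_mask = (groups == control_group).to_numpy()

    mets = list(signals.columns)
    plates = sorted(assay["plate"].unique())
    lods = pd.DataFrame(index=plates, columns=mets, dtype=float)
    conc = pd.DataFrame(index=signals.index, columns=mets, dtype=float)
    meta: dict = {"lod": {}, "lambda": {}, "shift": {}, "control_mean": {},
                  "control_sd": {}, "excluded": [], "tukey_adjusted": {},
                  "calibrated": {}}

    for met in mets:
        for p in plates:
            blanks = assay.query("well_type == 'blank' and plate == @p and "
                                 "metabolite == @met")["signal"]
            lods.loc[p, met] = compute_lod(blanks)
            cal = assay.query("well_type == 'calibrator' and plate == @p and "
                              "metabolite == @met")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = (fit_calibration(cal[["calib_conc", "signal"]].to_numpy())
                         if len(cal) else CalibrationCurve(identity=True))
            meta["calibrated"][met] = not curve.identity
            on_plate = plate_of == p
            conc.loc[on_plate, met] = curve.concentration(
                signals.loc[on_plate, met].to_numpy(float))
        meta["lod"][met] = lods[met].to_dict()

    excluded = flag_below_lod(signals, plate_of, lods)
    meta["excluded"] = [m for m in mets if excluded[m]]
    kept = [m for m in mets if not excluded[m]]

    z = pd.DataFrame(index=conc.index, columns=kept, dtype=float)
    for met in kept:
        x = conc[met]
        if x.isna().any():
            x = pd.Series(half_min_interpolate(x.to_numpy(float)), index=x.index)
        x = normalize_across_plates(x, plate_of, groups)
        vals = x.to_numpy(float)
        if boxcox:
            vals, shift = shift_positive(vals)
            lam = estimate_boxcox_lambda(vals)
            vals = apply_boxcox(vals, lam)
            meta["lambda"][met], meta["shift"][met] = lam, shift
        fenced = tukey_winsorize(vals, k=tukey_k)
        meta["tukey_adjusted"][met] = int((fenced != vals).sum())
        zvals = standardize_to_controls(fenced, control_mask)
        ctrl = fenced[control_mask]
        meta["control_mean"][met] = float(ctrl.mean())
        meta["control_sd"][met] = float(ctrl.std(ddof=1))
        z[met] = zvals

    return ProcessedMatrix(z=z, meta=meta)
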