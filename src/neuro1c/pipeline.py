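"""End-to-end orchestration: simulate -> preprocess -> differential -> SNP
-> composite scores -> expression-tree classifier, as one reproducible run.

A run is driven by a single :class:`RunConfig` (loadable from YAML); every
stage draws its randomness from a named substream of one root seed, and the
manifest written alongside the outputs records the config hash, the seeds
and the produced files, so re-running the same config reproduces every
output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neuro1c import gp, io, preprocessing, regression, scores, snp, synthetic
from neuro1c.synthetic import (CohortConfig, CouplingSpec, EffectSpec, LDSpec,
                               SNPSpec)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2**31)."""
    return int(np.random.SeedSequence(
        [int(root_seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def default_scenario() -> dict:
    """The default synthetic study conditions.

    Plants the dementia-shared cortical deficits (betaine, biotin, PLP, ThMP,
    pantothenic acid down ~0.5-0.7 control SD in both dementia groups), the
    AD-specific Hcy elevation and THF deficit with levodopa-dependent
    counterparts in PD-D, a one-carbon SNP panel with Hcy/betaine effects in
    both directions, a mutually exclusive (repulsion-phase) SNP pair, and
    group-enriched protective SNPs that separate PD-D from PD-ND.
    """
    effects = [
        EffectSpec("betaine", "AD-D", -0.6), EffectSpec("betaine", "PD-D", -0.6),
        EffectSpec("biotin", "AD-D", -0.73), EffectSpec("biotin", "PD-D", -0.6),
        EffectSpec("PLP", "AD-D", -0.51), EffectSpec("PLP", "PD-D", -0.5),
        EffectSpec("ThMP", "AD-D", -0.5), EffectSpec("ThMP", "PD-D", -0.51),
        EffectSpec("PA", "AD-D", -0.6), EffectSpec("PA", "PD-D", -0.64),
        EffectSpec("Hcy", "AD-D", 0.7),
        EffectSpec("Hcy", "PD-D", 1.4, levodopa_only=True),
        EffectSpec("THF", "AD-D", -0.53),
        EffectSpec("THF", "PD-D", -1.0, levodopa_only=True),
    ]
    couplings = [
        CouplingSpec("Hcy", "THF", -0.42),
        CouplingSpec("Hcy", "MTHF", -0.30),
        CouplingSpec("Hcy", "PLP", -0.29),
        CouplingSpec("Hcy", "ThPP", -0.19),
        CouplingSpec("Hcy", "ThMP", -0.19),
        CouplingSpec("Hcy", "PA", -0.16),
        CouplingSpec("betaine", "PLP", 0.55),
        CouplingSpec("betaine", "ThMP", 0.49),
        CouplingSpec("betaine", "biotin", 0.31),
        CouplingSpec("betaine", "PA", 0.22),
    ]
    impaired_odds = {"PD-MCI": 2.5, "PD-D": 2.0, "AD-D": 2.2}
    snps = [
        SNPSpec("rs234706", 0.30),
        SNPSpec("rs1801133", 0.30, "additive", effect_on=("Hcy", 0.5)),
        SNPSpec("rs1801131", 0.25),
        SNPSpec("rs1805087", 0.18, "dominant", effect_on=("betaine", -0.5),
                group_odds=impaired_odds),
        SNPSpec("rs1801394", 0.45, "recessive", effect_on=("Hcy", 0.8),
                group_odds=impaired_odds),
        SNPSpec("rs1806649", 0.20),
        SNPSpec("rs1051266", 0.45),
        SNPSpec("rs1801198", 0.45),
        SNPSpec("rs3733890", 0.30, "additive", effect_on=("betaine", 0.45)),
        SNPSpec("rs2853533", 0.25, "dominant", effect_on=("Hcy", -0.55),
                group_odds={"PD-D": 0.15, "PD-MCI": 0.6}),
        SNPSpec("rs10380", 0.18, "dominant", effect_on=("Hcy", -0.5),
                group_odds={"PD-D": 0.15, "PD-MCI": 0.6}),
    ]
    ld = [LDSpec(("rs1801133", "rs1801131"), 1.0, "repulsion")]
    return {"effects": effects, "snp_specs": snps, "ld_specs": ld,
            "couplings": couplings}


@dataclass
class RunConfig:
    """One run of the full pipeline.

    FDR thresholds follow the analysis convention: 0.05 for the metabolomic
    family, 0.10 for the genomic family.  The GP budget defaults to the
    scaled-down preset; the study-scale budget is selectable through
    ``gp_budget``.
    """

    out_dir: str = "runs/default"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scenario: dict = field(default_factory=default_scenario)
    n_plates: int = 2
    metabolomic_fdr: float = 0.05
    genomic_fdr: float = 0.10
    gp_target: tuple = ("PD-D", ("PD-CN", "PD-MCI"))
    gp_budget: gp.GPConfig = field(default_factory=gp.GPConfig.scaled_down)
    stages: tuple = ("simulate", "preprocess", "differential", "snp",
                     "scores", "gp")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw.pop("cohort"))
        if "gp_budget" in raw:
            kwargs["gp_budget"] = gp.GPConfig.scaled_down(**raw.pop("gp_budget"))
        raw.pop("scenario", None)  # scenario is code-defined; YAML overrides unsupported
        kwargs.update(raw)
        return cls(**kwargs)

    def hash(self) -> str:
        # output location does not affect scientific identity
        blob = repr((self.seed, self.cohort, sorted(
            (type(s).__name__, repr(s)) for v in self.scenario.values() for s in v),
            self.n_plates, self.metabolomic_fdr, self.genomic_fdr,
            self.gp_target, self.gp_budget, self.stages))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute every enabled stage, writing TSV/JSON outputs and a manifest
    into ``config.out_dir``.  Stage failures halt the run with a
    stage-named error after writing a partial manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "stages": {}, "versions": {"neuro1c": "0.1.0"}}
    state: dict = {}

    def record(stage, files):
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage),
                                     "outputs": [str(f) for f in files]}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    try:
        for stage in config.stages:
            files = _STAGES[stage](config, state, out)
            record(stage, files)
    except PipelineError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise PipelineError(stage, str(exc)) from exc
    write_report(out, state)
    return out


def _stage_simulate(config: RunConfig, state: dict, out: Path):
    seed = stage_seed(config.seed, "simulate")
    cohort = synthetic.CohortConfig(**{**config.cohort.__dict__, "seed": seed})
    subjects = synthetic.generate_subjects(cohort)
    sc = config.scenario
    genotypes = synthetic.generate_genotypes(
        subjects, sc["snp_specs"], sc["ld_specs"], seed=seed + 1)
    offsets = synthetic.snp_effect_offsets(genotypes, sc["snp_specs"])
    assay = synthetic.generate_raw_assay(
        subjects, sc["effects"], couplings=sc.get("couplings", ()),
        n_plates=config.n_plates, subject_offsets=offsets, seed=seed + 2)
    state.update(subjects=subjects, genotypes=genotypes, assay=assay)
    io.write_tsv(subjects, out / "subjects.tsv")
    io.write_tsv(assay, out / "assay.tsv")
    io.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
    return [out / "subjects.tsv", out / "assay.tsv", out / "genotypes.tsv"]


def _stage_preprocess(config: RunConfig, state: dict, out: Path):
    if "assay" not in state:
        raise PipelineError("preprocess", "no assay available (simulate stage disabled?)")
    processed = preprocessing.preprocess_assay(state["assay"], state["subjects"])
    z = processed.z
    subjects = state["subjects"].copy()
    if "DOPA" in z.columns:
        dopa = preprocessing.derive_dopa_indicators(
            z["DOPA"], state["subjects"].set_index("subject_id")["group"].reindex(z.index))
        dopa = dopa.reset_index(drop=True)
    else:
        dopa = None
    subjects = regression.prepare_covariates(subjects, dopa)
    for col in ("bmi", "education"):
        subjects = preprocessing.impute_conditional_mean(subjects, col)
    state.update(processed=processed, z=z, covariates=subjects)
    io.write_tsv(z.reset_index(), out / "processed_z.tsv")
    (out / "processed_meta.json").write_text(
        json.dumps(processed.meta, indent=2, default=float) + "\n")
    return [out / "processed_z.tsv", out / "processed_meta.json"]


def _analysis_metabolites(z: pd.DataFrame):
    return [m for m in z.columns if m != "DOPA"]


def _stage_differential(config: RunConfig, state: dict, out: Path):
    spec = regression.DesignSpec()
    z = state["z"][_analysis_metabolites(state["z"])]
    table = regression.run_differential(z, state["covariates"], spec)
    merged = regression.run_differential(
        z, state["covariates"],
        regression.DesignSpec(group_merges={"Dementia": ("AD-D", "PD-D")}))
    table = pd.concat([table, merged[merged["term"] == "Dementia"]],
                      ignore_index=True)
    state["differential"] = table
    io.write_tsv(table, out / "differential.tsv")
    return [out / "differential.tsv"]


def _stage_snp(config: RunConfig, state: dict, out: Path):
    if "genotypes" not in state:
        raise PipelineError("snp", "no genotype table available")
    genotypes = preprocessing.filter_rare_snps(
        state["genotypes"].reindex(state["z"].index))
    covs = state["covariates"]
    groups = covs.set_index("subject_id")["group"].reindex(genotypes.index)
    comparisons = {
        "PD-D vs PD-CN": (("PD-D",), ("PD-CN",)),
        "PD-MCI vs PD-CN+HC-CN": (("PD-MCI",), ("PD-CN", "HC-CN")),
        "AD-D vs HC-CN": (("AD-D",), ("HC-CN",)),
        "PD-D vs PD-ND": (("PD-D",), ("PD-CN", "PD-MCI")),
    }
    scan = snp.snp_subgroup_scan(genotypes, groups, comparisons)
    # SNP -> Hcy / betaine with objective covariates only, L+ samples excluded
    obj = covs[["sex_male", "age", "log_pmi", "log_storage"]].reset_index(drop=True)
    exclude = ((covs["dopa_pdd"] + covs["dopa_pdnd"]) > 0).to_numpy()
    assoc_tables = []
    for met in ("Hcy", "betaine"):
        if met not in state["z"].columns:
            continue
        y = state["z"][met].reset_index(drop=True)
        t = snp.snp_metabolite_assoc(genotypes.reset_index(drop=True), y, obj,
                                     exclude_mask=exclude, metabolite_kind=met)
        t.insert(0, "response", met)
        assoc_tables.append(t)
    assoc = pd.concat(assoc_tables, ignore_index=True) if assoc_tables else pd.DataFrame()
    ld_rows = []
    for s1, s2 in [ld.snp_pair for ld in config.scenario["ld_specs"]]:
        if s1 in genotypes.columns and s2 in genotypes.columns:
            r = snp.ld_stats(genotypes[s1], genotypes[s2])
            ld_rows.append({"snp1": s1, "snp2": s2, "D": r.D, "Dprime": r.Dprime,
                            "r": r.r, "chi2": r.chi2, "p": r.p})
    state.update(snp_scan=scan, snp_assoc=assoc, genotypes_filtered=genotypes,
                 ld_table=pd.DataFrame(ld_rows))
    io.write_tsv(scan, out / "snp_scan.tsv")
    io.write_tsv(assoc, out / "snp_assoc.tsv")
    io.write_tsv(state["ld_table"], out / "ld.tsv")
    return [out / "snp_scan.tsv", out / "snp_assoc.tsv", out / "ld.tsv"]


def _stage_scores(config: RunConfig, state: dict, out: Path):
    covs = state["covariates"]
    z = state["z"]
    vit_tables = []
    vitamins = [m for m in _analysis_metabolites(z) if m not in ("Hcy", "betaine")]
    for met in ("Hcy", "betaine"):
        if met not in z.columns:
            continue
        t = regression.run_covariate_response_assoc(
            z[met].to_numpy(), z[vitamins], covs)
        t.insert(0, "response", met)
        vit_tables.append(t)
    vit_assoc = pd.concat(vit_tables, ignore_index=True)
    sets = scores.build_risk_sets(state.get("snp_assoc", pd.DataFrame()), vit_assoc,
                                  snp_q_threshold=config.genomic_fdr,
                                  vitamin_fdr_threshold=config.metabolomic_fdr)
    groups = covs.set_index("subject_id")["group"]
    table, comparison = scores.score_table(
        state["genotypes_filtered"], z, sets, groups)
    state.update(vitamin_assoc=vit_assoc, risk_sets=sets, score_table=table,
                 score_comparison=comparison)
    io.write_tsv(vit_assoc, out / "vitamin_assoc.tsv")
    io.write_tsv(table.reset_index(), out / "scores.tsv")
    io.write_tsv(comparison, out / "score_comparison.tsv")
    return [out / "vitamin_assoc.tsv", out / "scores.tsv",
            out / "score_comparison.tsv"]


def _stage_gp(config: RunConfig, state: dict, out: Path):
    pos_label, neg_labels = config.gp_target
    covs = state["covariates"].set_index("subject_id")
    groups = covs["group"].reindex(state["z"].index)
    mask = groups.isin([pos_label, *neg_labels]).to_numpy()
    z = state["z"][_analysis_metabolites(state["z"])]
    feats = pd.concat([z, state["genotypes_filtered"]], axis=1).loc[mask]
    feats = feats.fillna(0.0)
    labels = (groups[mask] == pos_label).to_numpy()
    budget = gp.GPConfig(**{**config.gp_budget.__dict__,
                            "seed": stage_seed(config.seed, "gp")})
    result = gp.evolve(feats, labels, budget,
                       metabolites=list(z.columns),
                       snps=list(state["genotypes_filtered"].columns))
    state["gp_result"] = result
    payload = {"expression": result.expression, "fitness": result.fitness,
               "class_accuracies": list(result.class_accuracies),
               "operand_count": result.operand_count,
               "run_fitnesses": result.run_fitnesses,
               "target": [pos_label, list(neg_labels)]}
    (out / "gp_result.json").write_text(json.dumps(payload, indent=2) + "\n")
    return [out / "gp_result.json"]


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "differential": _stage_differential,
    "snp": _stage_snp,
    "scores": _stage_scores,
    "gp": _stage_gp,
}


def write_report(run_dir: Path, state: dict | None = None) -> Path:
    """Summary tables mirroring the heatmap / score-comparison layouts:
    a metabolite x contrast beta matrix with significance stars, the
    per-group score deltas, and a JSON index.  Missing stages produce a
    partial report with warnings."""
    run_dir = Path(run_dir)
    report: dict = {}
    diff_path = run_dir / "differential.tsv"
    if diff_path.exists():
        diff = pd.read_csv(diff_path, sep="\t")
        heat = diff.pivot_table(index="response", columns="term", values="beta")
        io.write_tsv(heat.round(3).reset_index(), run_dir / "report_heatmap.tsv")
        sig = diff[diff["fdr"] <= 0.05]
        report["significant_differential"] = (
            sig[["response", "term", "beta", "fdr"]].to_dict("records")
            if len(sig) else "no significant findings")
    else:
        warnings.warn("differential output missing; heatmap skipped")
    cmp_path = run_dir / "score_comparison.tsv"
    if cmp_path.exists():
        cmp = pd.read_csv(cmp_path, sep="\t")
        report["score_deltas"] = cmp[["score", "group", "delta_pct", "p"]].round(
            4).to_dict("records")
    else:
        warnings.warn("score comparison missing from report")
    gp_path = run_dir / "gp_result.json"
    if gp_path.exists():
        report["gp"] = json.loads(gp_path.read_text())
    (run_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return run_dir / "report.json"
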