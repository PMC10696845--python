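"""End-to-end orchestration: meta-analysis -> PRS -> PheWAS -> MR.

A single :class:`RunConfig` (YAML round-trippable, with every threshold
echoed into the run manifest) drives the full synthetic workflow:

1. simulate a genotyped cohort with a liability-threshold disease, ICD10
   records, paired-visit biomarkers with statin strata and female factors;
2. meta-analyse per-cohort disease GWAS replicates with genomic control and
   derive a PRS weight table;
3. score, standardize, build PCA covariates and run the three PheWAS trait
   sets in the female, male and female-sensitivity cohorts;
4. run two-sample MR in both directions on a simulated exposure/outcome GWAS
   pair, with F/Steiger filtering, IVW/Egger/weighted-median, leave-one-out,
   MR-PRESSO and within-group FDR.

All outputs are TSV plus a JSON manifest recording seeds, thresholds and the
counts at every filter; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotools, gwasio, mr, phewas, syndata

__all__ = ["RunConfig", "run_all", "significance_summary"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full synthetic run; defaults are the shipped profile."""

    outdir: str = "prsphewas_run"
    seed: int = 0
    cohort: syndata.SynthCohortConfig = field(
        default_factory=syndata.SynthCohortConfig)
    mr_sim: syndata.SynthMRConfig = field(default_factory=syndata.SynthMRConfig)
    gwas_cohort_ns: tuple[int, ...] = (15_000, 25_000)
    analysis_year: int = 2020
    phecode_min_count: int = 100
    gwas_p_max: float = 5e-8
    maf_min: float = 0.05
    miss_max: float = 0.05
    hwe_p_min: float = 1e-6
    ld_window_kb: float = 50.0
    ld_step: int = 5
    ld_r2_max: float = 0.2
    n_pcs: int = 10
    alpha: float = 0.05
    f_min: float = 10.0
    prs_average: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key, sub in (("cohort", syndata.SynthCohortConfig),
                         ("mr_sim", syndata.SynthMRConfig)):
            if key in d and isinstance(d[key], dict):
                if "maf_range" in d[key]:
                    d[key]["maf_range"] = tuple(d[key]["maf_range"])
                for tup in ("biomarkers", "gamma_abs_range", "eaf_range"):
                    if tup in d[key]:
                        d[key][tup] = tuple(d[key][tup])
                d[key] = sub(**d[key])
        if "gwas_cohort_ns" in d:
            d["gwas_cohort_ns"] = tuple(d["gwas_cohort_ns"])
        return cls(**d)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, na_rep="NA")


def _phecode_status(liability: np.ndarray, sex: np.ndarray,
                    pmap: gwasio.PhecodeMap, rng: np.random.Generator,
                    iids: list[str]) -> pd.DataFrame:
    """Comorbidity status table: per-phecode logistic link to the liability."""
    # (phecode, base prevalence, log-OR per liability SD, female-only)
    panel = [
        ("218", 0.10, 0.3, True), ("628", 0.08, 0.3, True),
        ("626.12", 0.08, 0.4, True), ("296.2", 0.12, 0.1, False),
        ("401", 0.25, 0.0, False), ("495", 0.12, 0.0, False),
        ("535", 0.08, 0.1, False), ("714", 0.06, 0.0, False),
        ("785", 0.12, 0.2, False), ("600", 0.10, 0.1, False),
        ("272.1", 0.15, 0.0, False),
    ]
    z = (liability - liability.mean()) / liability.std()
    table = {}
    for phe, prev, lor, female_only in panel:
        status = syndata.gen_binary_trait(z, lor, prev, rng)
        if female_only:
            status = status & (sex == "F")
        table[phe] = status
    return pd.DataFrame(table, index=pd.Index(iids, name="iid"))


def run_all(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "thresholds": {
        "phecode_min_count": cfg.phecode_min_count, "gwas_p_max": cfg.gwas_p_max,
        "maf_min": cfg.maf_min, "miss_max": cfg.miss_max,
        "hwe_p_min": cfg.hwe_p_min, "ld_window_kb": cfg.ld_window_kb,
        "ld_step": cfg.ld_step, "ld_r2_max": cfg.ld_r2_max,
        "n_pcs": cfg.n_pcs, "alpha": cfg.alpha, "f_min": cfg.f_min,
        "analysis_year": cfg.analysis_year}}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 100]))

    # --- stage 1: synthetic cohort -------------------------------------
    ccfg = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    G = syndata.gen_genotypes(ccfg)
    status, liability, effects = syndata.gen_disease(G, ccfg)
    iids = list(G.samples)
    sex = np.where(rng.random(G.n_samples) < 0.5, "F", "M")
    sex_s = pd.Series(sex, index=iids, name="sex")
    year_of_birth = pd.Series(rng.integers(1940, 1975, size=G.n_samples),
                              index=iids, name="year_of_birth")
    pmap = syndata.demo_phecode_map()

    status_table = _phecode_status(liability, sex, pmap, rng, iids)
    # endometriosis / adenomyosis at ICD level; disease only in females
    endo = pd.Series(status & (sex == "F"), index=iids)
    adeno = pd.Series(syndata.gen_binary_trait(
        np.zeros(G.n_samples), 0.0, 0.02, rng) & (sex == "F"), index=iids)
    status_table["endometriosis"] = endo
    status_table["adenomyosis"] = adeno
    records = syndata.gen_icd10_records(status_table, pmap,
                                        misdiagnosis_rate=0.02, seed=cfg.seed)
    _write(records, outdir / "icd10_records.tsv")
    manifest["stages"]["cohort"] = {
        "n_individuals": G.n_samples, "n_snps": G.n_variants,
        "n_female": int((sex == "F").sum()), "n_male": int((sex == "M").sum()),
        "n_disease_cases": int(endo.sum())}

    # --- stage 2: meta-analysis and PRS weights ------------------------
    cohort_stats = syndata.gen_gwas_cohorts(G, effects, list(cfg.gwas_cohort_ns),
                                            seed=cfg.seed)
    meta, meta_report = gwasio.meta_fixed(cohort_stats, apply_gc=True)
    gwasio.write_sumstats(meta, outdir / "meta_sumstats.tsv")
    weights = meta.table[["snp_id", "effect_allele", "beta"]].rename(
        columns={"beta": "weight"})
    genotools.write_weights(weights, outdir / "prs_weights.tsv")
    manifest["stages"]["meta"] = {
        "n_cohorts": len(cohort_stats),
        "lambda_gc": {k: float(v) for k, v in meta_report["lambda_gc"].items()},
        "n_snps": meta.n_variants,
        "n_dropped_alleles": len(meta_report["snps_dropped_alleles"])}

    # --- stage 3: genotype QC, PCA, scoring ----------------------------
    G_qc, qc_report = genotools.variant_qc(G, cfg.maf_min, cfg.miss_max,
                                           cfg.hwe_p_min)
    kept = genotools.ld_prune(G_qc, cfg.ld_window_kb, cfg.ld_step, cfg.ld_r2_max)
    G_pruned = G_qc.subset_variants(
        G_qc.variants["snp_id"].isin(kept).to_numpy())
    pcs = genotools.pca_covariates(G_pruned, k=cfg.n_pcs)
    _write(pcs, outdir / "pca_covariates.tsv", index=True)
    scores, score_report = genotools.prs_score(G, weights,
                                               average=cfg.prs_average)
    _write(scores.to_frame(), outdir / "prs_scores.tsv", index=True)
    manifest["stages"]["genotype_qc"] = qc_report
    manifest["stages"]["ld_prune"] = {"n_input": G_qc.n_variants,
                                      "n_kept": len(kept),
                                      "n_removed": G_qc.n_variants - len(kept)}
    manifest["stages"]["prs"] = {"n_weights": len(weights),
                                 "n_matched": score_report["n_matched"],
                                 "n_unmatched": len(score_report["unmatched"])}

    # --- stage 4: cohorts and PheWAS -----------------------------------
    case_flags = phewas.define_endometriosis_cases(records, iids)
    female = [i for i in iids if sex_s[i] == "F"]
    male = [i for i in iids if sex_s[i] == "M"]
    sensitivity = [i for i in female if not case_flags[i]]
    cohorts = {"female": female, "male": male, "sensitivity": sensitivity}
    manifest["stages"]["cohorts"] = {k: len(v) for k, v in cohorts.items()}

    age = (cfg.analysis_year - year_of_birth).astype(float).rename("age")
    visits, bio_covars = syndata.gen_biomarkers(G, effects, ccfg, sex=sex_s,
                                                prs_log_effect=0.05)
    factors_long = syndata.gen_female_factors(G, effects, seed=cfg.seed,
                                              shift=-0.1)
    stat_factors = phewas.statin_correction_factors(visits)
    _write(stat_factors, outdir / "statin_factors.tsv")
    stat_flags = phewas.flag_statin_affected(
        visits, bio_covars[["deprivation", "age", "age_gap"]].join(pcs),
        n_traits=len(ccfg.biomarkers))
    _write(stat_flags, outdir / "statin_flags.tsv")

    enrol = visits[visits["visit"] == "enrol"].pivot(index="iid",
                                                     columns="biomarker",
                                                     values="value")
    statin_enrol = (visits[visits["visit"] == "enrol"]
                    .groupby("iid")["statin"].first())
    adjusted = phewas.adjust_biomarkers(enrol, stat_flags, stat_factors,
                                        statin_enrol, sex_s)

    results_by_cohort: dict[str, dict[str, pd.DataFrame]] = {}
    n_traits_by_set: dict[str, int] = {}
    for name, members in cohorts.items():
        members_idx = pd.Index(members, name="iid")
        prs_z = pd.Series(genotools.zscore(scores.loc[members_idx]),
                          index=members_idx, name="prs_z")
        covars = pcs.loc[members_idx].join(age.loc[members_idx])

        table, included = phewas.build_phecode_table(
            records, pmap, members_idx, min_count=cfg.phecode_min_count)
        res_phe = phewas.phewas_logistic(prs_z, table, covars, pmap)
        bio_cov = (pcs.loc[members_idx]
                   .join(bio_covars.loc[members_idx, ["fasting_time", "age"]]))
        res_bio = phewas.phewas_biomarkers(prs_z, adjusted.loc[members_idx],
                                           bio_cov)
        sets = {"phecodes": res_phe, "biomarkers": res_bio}
        if name != "male":
            fem_factors = phewas.female_factor_qc(
                factors_long[factors_long["iid"].isin(members_idx)])
            fem_factors = fem_factors.reindex(members_idx)
            res_fem = phewas.phewas_female_factors(prs_z, fem_factors,
                                                   pcs.loc[members_idx])
            sets["female"] = res_fem
        for set_name, res in sets.items():
            n_traits = max(1, len(res))
            n_traits_by_set.setdefault(set_name, n_traits)
            thr = phewas.bonferroni_threshold(cfg.alpha, n_traits_by_set[set_name])
            res = res.assign(significant=res["p"] < thr)
            sets[set_name] = res
            _write(res, outdir / f"phewas_{name}_{set_name}.tsv")
        results_by_cohort[name] = sets
        manifest["stages"].setdefault("phewas", {})[name] = {
            s: {"n_traits": len(r),
                "n_significant": int(r["significant"].sum()),
                "n_flagged": int((~r["converged"]).sum())}
            for s, r in sets.items()}

    summary = significance_summary(results_by_cohort, cfg.alpha, n_traits_by_set)
    _write(summary, outdir / "significance_summary.tsv")

    # --- stage 5: two-sample MR, both directions -----------------------
    mcfg = dataclasses.replace(cfg.mr_sim, seed=cfg.seed + 1)
    exposure, outcome, truth = syndata.gen_two_sample_sumstats(mcfg)
    gwasio.write_sumstats(exposure, outdir / "mr_exposure_sumstats.tsv")
    gwasio.write_sumstats(outcome, outdir / "mr_outcome_sumstats.tsv")
    mr_results: list[mr.MRResult] = []
    loo_tables = []
    mr_counts: dict = {}
    for direction, (ss_e, ss_o) in {
            "exposure->outcome": (exposure, outcome),
            "outcome->exposure": (outcome, exposure)}.items():
        counts = {}
        try:
            inst = mr.select_instruments(ss_e, p_max=cfg.gwas_p_max)
        except ValueError:
            mr_counts[direction] = {"instruments": 0}
            continue
        counts["instruments"] = inst.n_variants
        mri, harm_report = mr.harmonize(inst, ss_o)
        counts["harmonized"] = len(mri)
        mri, _ = mr.f_statistics(mri, f_min=cfg.f_min)
        counts["after_f_filter"] = len(mri)
        mri, _ = mr.steiger_filter(mri)
        counts["after_steiger"] = len(mri)
        mr_counts[direction] = counts
        if len(mri) < 4:
            continue
        mr_results.append(mr.ivw(mri, direction))
        mr_results.append(mr.mr_egger(mri, direction))
        mr_results.append(mr.weighted_median(mri, seed=cfg.seed + 2,
                                             direction=direction))
        raw, adj, _ = mr.mr_presso(mri, seed=cfg.seed + 3, direction=direction)
        mr_results.extend([raw, adj])
        loo = mr.leave_one_out(mri, cfg.alpha, direction)
        loo.insert(0, "direction", direction)
        loo_tables.append(loo)
    res_table = mr.results_table(mr_results)
    res_table = mr.fdr_within_groups(res_table)
    _write(res_table, outdir / "mr_results.tsv")
    if loo_tables:
        _write(pd.concat(loo_tables, ignore_index=True),
               outdir / "mr_leave_one_out.tsv")
    manifest["stages"]["mr"] = {"counts": mr_counts,
                                "true_b": float(truth["true_b"]),
                                "n_methods": len(mr_results)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def significance_summary(results_by_cohort: dict[str, dict[str, pd.DataFrame]],
                         alpha: float, n_traits_by_set: dict[str, int]
                         ) -> pd.DataFrame:
    """Cross-cohort replication table for traits significant anywhere.

    Per trait: the Bonferroni and nominal significance verdicts in each
    cohort, and a replication label ('replicated' when Bonferroni-significant
    in another cohort, 'nominal replication' when p < alpha there).  Traits
    significant nowhere are absent.
    """
    rows = []
    for set_name, n_traits in n_traits_by_set.items():
        thr = alpha / n_traits
        traits: dict[str, dict] = {}
        for cohort, sets in results_by_cohort.items():
            if set_name not in sets:
                continue
            for r in sets[set_name].itertuples(index=False):
                rec = traits.setdefault(r.trait, {"set": set_name,
                                                  "trait": r.trait})
                rec[f"p_{cohort}"] = r.p
                rec[f"sig_{cohort}"] = bool(r.p < thr) if np.isfinite(r.p) else False
        for trait, rec in traits.items():
            sig_cols = [c for c in rec if c.startswith("sig_")]
            if not any(rec[c] for c in sig_cols):
                continue
            p_cols = [c for c in rec if c.startswith("p_")]
            n_bonf = sum(bool(rec[c]) for c in sig_cols)
            n_nominal = sum(1 for c in p_cols
                            if np.isfinite(rec[c]) and rec[c] < alpha)
            if n_bonf > 1:
                rec["replication"] = "replicated"
            elif n_nominal > 1:
                rec["replication"] = "nominal replication"
            else:
                rec["replication"] = "not replicated"
            rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=["set", "trait", "replication"])
    df = pd.DataFrame(rows)
    front = ["set", "trait", "replication"]
    cols = front + sorted(c for c in df.columns if c not in front)
    return df[cols].sort_values(["set", "trait"],
                                kind="mergesort").reset_index(drop=True)
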