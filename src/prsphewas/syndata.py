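"""Synthetic biobank cohorts and two-sample GWAS pairs with known ground truth.

Every downstream stage of the pipeline (scoring, PheWAS, statin machinery,
Mendelian randomisation) is testable against these generators because the
simulated truth (per-SNP causal effects, liability, statin multipliers,
pleiotropic effects) is returned alongside the data.  All sampling is routed
through one explicit :class:`numpy.random.Generator` derived from the config
seed; nothing touches global random state.

The disease model is a liability threshold: a standardized latent liability is
the sum of a genetic score (explaining ``h2_liability`` of the variance) and
normal noise, and individuals above the (1 - prevalence) quantile are cases.
Biomarkers are lognormal with a multiplicative statin effect applied at
on-statin visits, reproducing the paired-visit design used to derive statin
correction factors.  Two-sample GWAS pairs draw per-SNP exposure effects and
build outcome effects as ``true_b * gamma + alpha + noise`` with the pleiotropy
structure selected by ``pleiotropy_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

from .genotools import VARIANT_COLUMNS, GenotypeMatrix
from .gwasio import SUMSTATS_COLUMNS, PhecodeMap, SummaryStats, read_phecode_map

__all__ = [
    "SynthCohortConfig",
    "SynthMRConfig",
    "gen_genotypes",
    "gen_disease",
    "gen_icd10_records",
    "gen_biomarkers",
    "gen_female_factors",
    "gen_two_sample_sumstats",
    "gen_gwas_cohorts",
    "gen_binary_trait",
    "demo_phecode_map",
    "write_demo_phecode_map",
    "DEFAULT_BIOMARKERS",
]

DEFAULT_BIOMARKERS = ("triglycerides", "ldl_cholesterol", "hdl_cholesterol",
                      "testosterone", "calcium", "urate")

#: lognormal location/scale of the latent biomarker distributions
_BIOMARKER_PARAMS = {
    "triglycerides": (0.3, 0.45), "ldl_cholesterol": (1.2, 0.25),
    "hdl_cholesterol": (0.35, 0.25), "testosterone": (0.2, 0.5),
    "calcium": (0.87, 0.04), "urate": (5.6, 0.25),
}


@dataclass
class SynthCohortConfig:
    """Parameters of the synthetic biobank-like cohort."""

    n_individuals: int = 2000
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    prevalence: float = 0.1
    h2_liability: float = 0.4
    n_causal: int = 60
    statin_usage_rate: float = 0.2
    statin_effect: float = 0.75
    statin_noise_sd: float = 0.05
    biomarkers: tuple[str, ...] = DEFAULT_BIOMARKERS
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("non-positive cohort dimensions")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 <= self.h2_liability <= 1.0):
            raise ValueError("h2_liability must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        if self.statin_effect <= 0:
            raise ValueError("statin_effect must be strictly positive")


@dataclass
class SynthMRConfig:
    """Parameters of a simulated exposure/outcome GWAS pair.

    ``pleiotropy_mode``: 'none' (all alphas exactly zero), 'balanced'
    (zero-mean alphas), 'directional' (alphas with mean ``pleiotropy_mean``) or
    'inside_violating' (alphas correlated with the exposure effects).
    ``n_outliers`` instruments additionally receive a gross common-sign alpha
    shift of ``outlier_shift``.
    """

    k_instruments: int = 30
    true_b: float = -0.2
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.005
    pleiotropy_mean: float = 0.01
    n_exposure: int = 200_000
    n_outcome: int = 100_000
    n_outliers: int = 0
    outlier_shift: float = 0.1
    gamma_abs_range: tuple[float, float] = (0.03, 0.10)
    eaf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.k_instruments < 2:
            raise ValueError("need at least 2 instruments")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ValueError("GWAS sample sizes must be >= 100")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_outliers > self.k_instruments:
            raise ValueError("more outliers than instruments")


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


def _variant_frame(rng: np.random.Generator, n_snps: int, freqs: np.ndarray,
                   prefix: str = "rs", spaced: bool = False) -> pd.DataFrame:
    chroms = (np.arange(n_snps) % 22) + 1
    pos = np.zeros(n_snps, dtype=int)
    for c in range(1, 23):
        m = chroms == c
        if spaced:
            # guaranteed > 2 Mb apart: instruments behave as unlinked loci
            pos[m] = (np.arange(m.sum()) * 5_000_000
                      + rng.integers(1, 2_000_000, size=m.sum()))
        else:
            pos[m] = np.sort(rng.integers(1, 50_000_000, size=m.sum()))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    a1 = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    a2 = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return pd.DataFrame({
        "snp_id": [f"{prefix}{i + 1}" for i in range(n_snps)],
        "chrom": chroms.astype(str), "pos": pos,
        "counted_allele": a1, "other_allele": a2, "freq": freqs,
    }, columns=VARIANT_COLUMNS)


def gen_genotypes(cfg: SynthCohortConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes at independent SNPs; missing calls at random."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    dosages = rng.binomial(2, freqs, size=(cfg.n_individuals, cfg.n_snps)
                           ).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
    variants = _variant_frame(rng, cfg.n_snps, freqs)
    samples = [f"iid{i + 1}" for i in range(cfg.n_individuals)]
    return GenotypeMatrix(samples, variants, dosages)


def _genetic_score(G: GenotypeMatrix, effects: pd.DataFrame) -> np.ndarray:
    """True genetic value: dosage-weighted sum of causal effects (mean-imputed)."""
    meta = G.variants.set_index("snp_id")
    score = np.zeros(G.n_samples)
    for row in effects.itertuples(index=False):
        j = meta.index.get_loc(row.snp_id)
        d = G.dosages[:, j]
        d = np.where(np.isnan(d), 2.0 * meta.at[row.snp_id, "freq"], d)
        score += row.beta * d
    return score


def gen_disease(G: GenotypeMatrix, cfg: SynthCohortConfig
                ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Liability-threshold disease status.

    Returns (case status, liability, causal-effect table).  The genetic score
    over ``n_causal`` SNPs is standardized to explain ``h2_liability`` of the
    liability variance; the case threshold is the standard-normal
    (1 - prevalence) quantile.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    idx = rng.choice(cfg.n_snps, size=cfg.n_causal, replace=False)
    betas = rng.normal(0.0, 1.0, size=cfg.n_causal)
    effects = pd.DataFrame({
        "snp_id": G.variants["snp_id"].to_numpy()[idx],
        "effect_allele": G.variants["counted_allele"].to_numpy()[idx],
        "beta": betas,
    })
    g = _genetic_score(G, effects)
    sd = g.std()
    g_std = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    noise = rng.normal(size=G.n_samples)
    h2 = cfg.h2_liability
    liability = np.sqrt(h2) * g_std + np.sqrt(1.0 - h2) * noise
    threshold = stats.norm.ppf(1.0 - cfg.prevalence)
    status = liability > threshold
    return status, liability, effects


def gen_icd10_records(status_table: pd.DataFrame, phecode_map: PhecodeMap,
                      misdiagnosis_rate: float = 0.0, seed: int = 0
                      ) -> pd.DataFrame:
    """ICD10 diagnosis records (long: iid, code) from a phecode status table.

    ``status_table``: boolean DataFrame indexed by individual id.  Columns are
    phecodes from ``phecode_map``; the special columns ``endometriosis`` and
    ``adenomyosis`` emit one of N80.1-N80.9 and N80.0 respectively, so the
    case-definition logic downstream sees realistic N80.* structure.  With
    probability ``misdiagnosis_rate`` an individual receives one extra random
    non-N80 code from the map.
    """
    rng = np.random.default_rng(seed)
    endo_codes = [f"N80.{i}" for i in range(1, 10)]
    noise_pool = sorted(c for c in phecode_map.icd_to_phecode
                        if not c.startswith("N80"))
    records: list[tuple[str, str]] = []
    for col in status_table.columns:
        if col == "endometriosis":
            pool = endo_codes
        elif col == "adenomyosis":
            pool = ["N80.0"]
        else:
            pool = phecode_map.codes_for(str(col))
            if not pool:
                raise ValueError(f"phecode {col!r} has no ICD10 codes in the map")
        flagged = status_table.index[status_table[col].astype(bool)]
        codes = rng.choice(pool, size=len(flagged))
        records.extend(zip(flagged, codes))
    if misdiagnosis_rate > 0 and noise_pool:
        hit = rng.random(len(status_table)) < misdiagnosis_rate
        for iid in status_table.index[hit]:
            records.append((iid, rng.choice(noise_pool)))
    df = pd.DataFrame(records, columns=["iid", "code"])
    return df.sort_values(["iid", "code"], kind="mergesort").reset_index(drop=True)


def gen_biomarkers(G: GenotypeMatrix, effects: pd.DataFrame | None,
                   cfg: SynthCohortConfig, sex: pd.Series | None = None,
                   prs_log_effect: float = 0.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-visit biomarker table with statin strata.

    Returns (visit table, covariates).  The visit table is long with columns
    (iid, sex, biomarker, visit in {enrol, repeat}, value, statin).  Statin
    users split evenly into an enrolment-onward stratum and a repeat-visit-only
    stratum; on-statin values are latent x ``statin_effect`` x lognormal noise
    with log-SD ``statin_noise_sd``.  When ``effects`` is supplied, the
    standardized genetic score shifts log biomarker values by
    ``prs_log_effect`` per SD.  Covariates: age, Townsend-style deprivation
    stand-in, fasting time, age difference between visits.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = G.n_samples
    iids = list(G.samples)
    if sex is None:
        sex = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=iids)
    if effects is not None and prs_log_effect != 0.0:
        g = _genetic_score(G, effects)
        g = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(n)
    else:
        g = np.zeros(n)

    u = rng.random(n)
    never = u >= cfg.statin_usage_rate
    enrol_onward = (~never) & (rng.random(n) < 0.5)
    repeat_only = (~never) & (~enrol_onward)
    statin_enrol = enrol_onward
    statin_repeat = enrol_onward | repeat_only

    rows = []
    for bm in cfg.biomarkers:
        mu, sigma = _BIOMARKER_PARAMS.get(bm, (0.0, 0.3))
        latent = np.exp(mu + sigma * rng.normal(size=n) + prs_log_effect * g)
        for visit, on in (("enrol", statin_enrol), ("repeat", statin_repeat)):
            noise = (np.exp(rng.normal(0.0, cfg.statin_noise_sd, size=n))
                     if cfg.statin_noise_sd > 0 else np.ones(n))
            value = latent * noise * np.where(on, cfg.statin_effect, 1.0)
            rows.append(pd.DataFrame({
                "iid": iids, "sex": sex.to_numpy(), "biomarker": bm,
                "visit": visit, "value": value, "statin": on,
                "latent": latent,
            }))
    visits = pd.concat(rows, ignore_index=True)
    covars = pd.DataFrame({
        "age": rng.integers(40, 70, size=n).astype(float),
        "deprivation": rng.normal(0.0, 3.0, size=n),
        "fasting_time": rng.integers(0, 12, size=n).astype(float),
        "age_gap": rng.uniform(2.0, 6.0, size=n),
    }, index=pd.Index(iids, name="iid"))
    return visits, covars


_FACTOR_CENTERS = {
    "menarche_age": (13.0, 1.6), "menopause_age": (50.0, 4.0),
    "cycle_length": (28.0, 3.0), "parity": None,
    "first_birth_age": (26.0, 4.0), "first_child_birth_weight": (7.4, 1.2),
}

_FACTOR_OUTLIER_DRAWS = {
    "menarche_age": (4.0, 7.0), "menopause_age": (30.0, 39.0),
    "cycle_length": (15.0, 21.0), "first_birth_age": (10.0, 13.0),
    "first_child_birth_weight": (0.5, 2.5),
}


def gen_female_factors(G: GenotypeMatrix, effects: pd.DataFrame | None,
                       seed: int = 0, shift: float = 0.0,
                       out_of_range_rate: float = 0.05) -> pd.DataFrame:
    """Reproductive-factor table (long: iid, factor, visit, value).

    Values are drawn around population-realistic centres; the standardized
    genetic score shifts each factor by ``shift`` (raw units per SD) when
    ``effects`` is supplied.  A fraction ``out_of_range_rate`` of values falls
    outside the downstream QC windows, and parities >= 4 occur, so the QC and
    collapsing rules are exercised.  Two visits are emitted for a random third
    of individuals (the visit-selection rules then matter).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n = G.n_samples
    if effects is not None and shift != 0.0:
        g = _genetic_score(G, effects)
        g = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(n)
    else:
        g = np.zeros(n)
    rows = []
    two_visits = rng.random(n) < (1.0 / 3.0)
    for factor, params in _FACTOR_CENTERS.items():
        if factor == "parity":
            base = rng.poisson(1.8, size=n).astype(float)
            values = np.maximum(0.0, np.round(base + shift * g))
        else:
            mu, sd = params
            values = rng.normal(mu, sd, size=n) + shift * g
            lo, hi = _FACTOR_OUTLIER_DRAWS[factor]
            out = rng.random(n) < out_of_range_rate
            values = np.where(out, rng.uniform(lo, hi, size=n), values)
            if factor in ("menarche_age", "menopause_age", "cycle_length"):
                values = np.round(values)
            elif factor == "first_child_birth_weight":
                # reported in half-pound increments
                values = np.round(values * 2.0) / 2.0
        rows.append(pd.DataFrame({"iid": G.samples, "factor": factor,
                                  "visit": 0, "value": values}))
        # follow-up visit: parity can only grow; other factors re-reported
        v2 = values.copy()
        if factor == "parity":
            v2 = values + rng.binomial(1, 0.3, size=n)
        else:
            v2 = values + rng.normal(0.0, 0.2, size=n)
        rows.append(pd.DataFrame({"iid": np.asarray(G.samples)[two_visits],
                                  "factor": factor, "visit": 1,
                                  "value": v2[two_visits]}))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["iid", "factor", "visit"],
                          kind="mergesort").reset_index(drop=True)


def gen_two_sample_sumstats(cfg: SynthMRConfig
                            ) -> tuple[SummaryStats, SummaryStats, dict]:
    """Simulated exposure/outcome GWAS pair with known causal effect.

    Exposure effects gamma_j are drawn with |gamma| uniform in
    ``gamma_abs_range`` and random sign; standard errors follow the
    large-sample approximation 1/sqrt(2 p q N).  Outcome effects are
    ``true_b * gamma_j + alpha_j`` plus sampling noise, with alpha_j set by the
    pleiotropy mode.  The truth record carries gamma, alpha and the outlier
    indices.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_instruments
    eaf = rng.uniform(*cfg.eaf_range, size=k)
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_outcome)
    # instruments oriented to the exposure-increasing allele (the convention
    # for harmonized instrument sets), so gamma > 0
    gamma = rng.uniform(*cfg.gamma_abs_range, size=k)

    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=k)
    elif cfg.pleiotropy_mode == "directional":
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k)
    else:  # inside_violating: alpha correlated with gamma
        rho = 0.7
        gsd = gamma.std() if gamma.std() > 0 else 1.0
        alpha = (rho * cfg.pleiotropy_sd * gamma / gsd
                 + np.sqrt(1 - rho ** 2) * rng.normal(0.0, cfg.pleiotropy_sd,
                                                      size=k))
    outlier_idx = np.array([], dtype=int)
    if cfg.n_outliers > 0:
        outlier_idx = rng.choice(k, size=cfg.n_outliers, replace=False)
        alpha = alpha.copy()
        alpha[outlier_idx] += cfg.outlier_shift

    beta_x = gamma + rng.normal(0.0, se_x)
    beta_y = cfg.true_b * gamma + alpha + rng.normal(0.0, se_y)

    variants = _variant_frame(rng, k, eaf, spaced=True)
    base = variants.rename(columns={"counted_allele": "effect_allele"})

    def _ss(trait, beta, se, n):
        t = base.copy()
        t["beta"] = beta
        t["se"] = se
        t["p"] = 2.0 * stats.norm.sf(np.abs(beta / se))
        t["eaf"] = eaf
        t["n"] = float(n)
        return SummaryStats(trait, "synthetic", t[SUMSTATS_COLUMNS])

    exposure = _ss("exposure", beta_x, se_x, cfg.n_exposure)
    outcome = _ss("outcome", beta_y, se_y, cfg.n_outcome)
    truth = {"true_b": cfg.true_b, "gamma": gamma, "alpha": alpha,
             "outliers": np.sort(outlier_idx),
             "outlier_snps": sorted(variants["snp_id"].iloc[outlier_idx])}
    return exposure, outcome, truth


def gen_gwas_cohorts(G: GenotypeMatrix, effects: pd.DataFrame,
                     cohort_ns: list[int], seed: int = 0,
                     effect_scale: float = 0.05) -> list[SummaryStats]:
    """Per-cohort disease GWAS replicates around the cohort's true effects.

    Emulates the multi-cohort summary statistics fed into the fixed-effect
    meta-analysis: every cohort observes ``effect_scale * beta_true`` for the
    causal SNPs (0 elsewhere) plus sampling noise at its own sample size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    v = G.variants
    truth = pd.Series(0.0, index=v["snp_id"])
    truth.loc[effects["snp_id"].to_numpy()] = (effect_scale
                                               * effects["beta"].to_numpy())
    out = []
    for i, n in enumerate(cohort_ns):
        se = 1.0 / np.sqrt(2.0 * v["freq"].to_numpy()
                           * (1.0 - v["freq"].to_numpy()) * n)
        beta = truth.to_numpy() + rng.normal(0.0, se)
        t = pd.DataFrame({
            "snp_id": v["snp_id"], "chrom": v["chrom"], "pos": v["pos"],
            "effect_allele": v["counted_allele"],
            "other_allele": v["other_allele"], "eaf": v["freq"],
            "beta": beta, "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(beta / se)), "n": float(n),
        }, columns=SUMSTATS_COLUMNS)
        out.append(SummaryStats("disease", f"cohort{i + 1}", t))
    return out


def gen_binary_trait(score_z: np.ndarray, log_or: float, prevalence: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Bernoulli trait from a logistic model on a standardized score."""
    intercept = np.log(prevalence / (1.0 - prevalence))
    p = 1.0 / (1.0 + np.exp(-(intercept + log_or * np.asarray(score_z))))
    return rng.random(len(p)) < p


# ---------------------------------------------------------------------------
# built-in demonstration phecode map (synthetic, PheWAS-catalog layout)

_DEMO_ICD_MAP = """\
ICD10,PHECODE
N80.0,615
N80.1,615
N80.2,615
N80.3,615
N80.4,615
N80.5,615
N80.6,615
N80.7,615
N80.8,615
N80.9,615
D25.0,218
D25.9,218
N83.0,628
N83.2,628
N92.0,626.12
F32.9,296.2
F33.1,296.2
I10,401
J45.9,495
K29.7,535
M06.9,714
R10.4,785
N40,600
E78.5,272.1
A41.9,038
H40.9,365
L40.9,696
Q21.1,747.1
S52.5,804
"""

_DEMO_DEFINITIONS = """\
phecode,phenotype,category
615,Endometriosis,genitourinary
218,Uterine leiomyoma,neoplasms
628,Ovarian cyst,genitourinary
626.12,Excessive or frequent menstruation,genitourinary
296.2,Depression,mental disorders
401,Hypertension,circulatory system
495,Asthma,respiratory
535,Gastritis and duodenitis,digestive
714,Rheumatoid arthritis,musculoskeletal
785,Abdominal pain,symptoms
600,Hyperplasia of prostate,genitourinary
272.1,Hyperlipidemia,endocrine/metabolic
038,Septicemia,infectious diseases
365,Glaucoma,sense organs
696,Psoriasis,dermatologic
747.1,Cardiac congenital anomalies,congenital anomalies
804,Fracture of arm,injuries & poisonings
"""


def demo_phecode_map() -> PhecodeMap:
    """Small synthetic phecode map in the PheWAS-catalog CSV layout."""
    return read_phecode_map(StringIO(_DEMO_ICD_MAP), StringIO(_DEMO_DEFINITIONS))


def write_demo_phecode_map(icd_path, definitions_path) -> None:
    with open(icd_path, "w") as fh:
        fh.write(_DEMO_ICD_MAP)
    with open(definitions_path, "w") as fh:
        fh.write(_DEMO_DEFINITIONS)
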