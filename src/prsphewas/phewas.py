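"""Phenome-wide association of a PRS z-score with phecodes, biomarkers and
female-specific reproductive factors.

Three trait sets, three model families:

* phecodes: logistic regression of case status on the PRS z-score with the
  first genetic PCs and age as covariates;
* blood/urine biomarkers: linear regression of the natural-log biomarker,
  after multiplicative statin correction of affected biomarkers in individuals
  on statins at enrolment;
* female-specific factors: linear regression on inverse-rank-normal transformed
  values (age at menarche, age at first birth) or proportional-odds ordinal
  logistic regression (menopause age, cycle length, parity, first-child birth
  weight), with p-values from comparing t-values to a standard normal.

Every tested trait yields exactly one result row; fits that fail to converge
are flagged with a diagnostic rather than dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .gwasio import PhecodeMap

__all__ = [
    "ASSOC_COLUMNS",
    "define_endometriosis_cases",
    "build_phecode_table",
    "phewas_logistic",
    "statin_correction_factors",
    "flag_statin_affected",
    "adjust_biomarkers",
    "phewas_biomarkers",
    "female_factor_qc",
    "phewas_female_factors",
    "bonferroni_threshold",
    "inverse_rank_normal",
    "FEMALE_FACTOR_MODELS",
    "FEMALE_FACTOR_RANGES",
]

ASSOC_COLUMNS = ["trait", "category", "model", "estimate", "se", "p",
                 "n", "n_cases", "converged", "note"]

#: model family per female-specific factor (paper defaults; overridable)
FEMALE_FACTOR_MODELS = {
    "menarche_age": "linear",
    "first_birth_age": "linear",
    "menopause_age": "ordinal",
    "cycle_length": "ordinal",
    "parity": "ordinal",
    "first_child_birth_weight": "ordinal",
}

#: QC windows (inclusive) per factor; values outside are excluded
FEMALE_FACTOR_RANGES = {
    "menarche_age": (8.0, 20.0),
    "first_birth_age": (14.0, 43.0),
    "menopause_age": (40.0, 63.0),
    "cycle_length": (22.0, 36.0),
    "first_child_birth_weight": (3.0, 12.0),
}

_ENDO_CODES = {f"N80.{i}" for i in range(1, 10)}


def define_endometriosis_cases(records: pd.DataFrame,
                               individuals: pd.Index | list) -> pd.Series:
    """Endometriosis case flags from ICD10 records.

    Case iff any of N80.1-N80.9 is present; an individual with only N80.0
    (adenomyosis, a distinct disease) is not a case.  ``records`` is long with
    columns (iid, code); ``individuals`` enumerates the cohort so code-free
    individuals get an explicit False.
    """
    hits = records.loc[records["code"].isin(_ENDO_CODES), "iid"].unique()
    flags = pd.Series(False, index=pd.Index(individuals, name="iid"),
                      name="endometriosis_case")
    flags.loc[flags.index.intersection(hits)] = True
    return flags


def build_phecode_table(records: pd.DataFrame, phecode_map: PhecodeMap,
                        individuals: pd.Index | list, min_count: int = 100
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Binary phecode indicator table; phecodes carried by >= min_count kept.

    ICD10 codes absent from the map are ignored; multiple codes mapping to one
    phecode count each individual once.  Controls for a phecode are all
    individuals without it (no exclusion-range logic).
    """
    rec = records.copy()
    rec["phecode"] = rec["code"].map(phecode_map.icd_to_phecode)
    rec = rec.dropna(subset=["phecode"]).drop_duplicates(["iid", "phecode"])
    idx = pd.Index(individuals, name="iid")
    table = pd.DataFrame(False, index=idx, columns=phecode_map.phecodes)
    rec = rec[rec["iid"].isin(idx)]
    for phe, grp in rec.groupby("phecode"):
        table.loc[grp["iid"], phe] = True
    counts = table.sum(axis=0)
    included = [p for p in table.columns if counts[p] >= min_count]
    return table[included], included


def _fit_result_row(trait, category, model, n, n_cases=np.nan):
    return {"trait": trait, "category": category, "model": model,
            "estimate": np.nan, "se": np.nan, "p": np.nan, "n": n,
            "n_cases": n_cases, "converged": False, "note": ""}


def phewas_logistic(prs_z: pd.Series, phecode_table: pd.DataFrame,
                    covariates: pd.DataFrame,
                    phecode_map: PhecodeMap | None = None) -> pd.DataFrame:
    """Logistic PheWAS: one maximum-likelihood fit per phecode.

    The estimate is the log-odds of the phecode per SD of PRS, adjusted for
    the supplied covariates (PCs + age).  Non-converged or separated fits are
    flagged via ``converged``/``note`` with no estimate.
    """
    idx = phecode_table.index
    X = pd.concat([prs_z.rename("prs_z").loc[idx], covariates.loc[idx]], axis=1)
    X = sm.add_constant(X, prepend=True)
    rows = []
    for phe in phecode_table.columns:
        y = phecode_table[phe].astype(float)
        category = phecode_map.category(phe) if phecode_map is not None else ""
        row = _fit_result_row(phe, category, "logistic", len(y), int(y.sum()))
        if y.sum() == 0 or y.sum() == len(y):
            row["note"] = "no variation in outcome"
            rows.append(row)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False):
                row["note"] = "did not converge"
            else:
                row.update(estimate=float(fit.params["prs_z"]),
                           se=float(fit.bse["prs_z"]),
                           p=float(fit.pvalues["prs_z"]), converged=True)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            row["note"] = f"fit failed: {type(exc).__name__}"
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def _paired_values(visits: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(iid, biomarker) frame with enrol/repeat values and statin flags."""
    wide = visits.pivot_table(index=["iid", "sex", "biomarker"],
                              columns="visit", values=["value", "statin"],
                              aggfunc="first")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()


def statin_correction_factors(visits: pd.DataFrame) -> pd.DataFrame:
    """Sex-specific multiplicative statin correction factors.

    Individuals on statins at the first repeat visit but not at enrolment
    contribute the ratio (on-statin repeat value) / (pre-statin enrolment
    value); the factor is the mean ratio per sex and biomarker.  Biomarkers
    with no qualifying individuals for a sex are reported with a NaN factor.
    """
    wide = _paired_values(visits)
    qual = wide[(wide["statin_repeat"].astype(bool))
                & (~wide["statin_enrol"].astype(bool))].copy()
    if qual.empty:
        raise ValueError("no individuals on statins at the repeat visit only")
    qual["ratio"] = qual["value_repeat"] / qual["value_enrol"]
    out = []
    for (sex, bm), grp in qual.groupby(["sex", "biomarker"]):
        out.append({"sex": sex, "biomarker": bm,
                    "factor": float(grp["ratio"].mean()),
                    "n": int(len(grp))})
    # biomarkers present in the data but with no qualifying pair for a sex
    all_pairs = {(s, b) for s in visits["sex"].unique()
                 for b in visits["biomarker"].unique()}
    have = {(r["sex"], r["biomarker"]) for r in out}
    for sex, bm in sorted(all_pairs - have):
        out.append({"sex": sex, "biomarker": bm, "factor": np.nan, "n": 0})
    return pd.DataFrame(out).sort_values(["sex", "biomarker"]
                                         ).reset_index(drop=True)


def flag_statin_affected(visits: pd.DataFrame, covariates: pd.DataFrame,
                         n_traits: int = 34, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Flag biomarkers whose level statins shift, per sex.

    Among individuals on statins at the repeat visit only, the log ratio of
    pre-statin to on-statin value is regressed on deprivation, PCs, age at
    enrolment and the inter-visit age gap; the biomarker is flagged when the
    adjusted mean log-ratio (the intercept) departs from zero at
    p < alpha / n_traits.
    """
    threshold = alpha / n_traits
    wide = _paired_values(visits)
    qual = wide[(wide["statin_repeat"].astype(bool))
                & (~wide["statin_enrol"].astype(bool))].copy()
    qual["log_ratio"] = np.log(qual["value_enrol"] / qual["value_repeat"])
    rows = []
    for (sex, bm), grp in qual.groupby(["sex", "biomarker"]):
        cov = covariates.loc[grp["iid"]]
        X = sm.add_constant(cov.reset_index(drop=True), prepend=True)
        fit = sm.OLS(grp["log_ratio"].to_numpy(), X).fit()
        est, p = float(fit.params["const"]), float(fit.pvalues["const"])
        rows.append({"sex": sex, "biomarker": bm, "estimate": est, "p": p,
                     "flagged": bool(p < threshold), "n": int(len(grp)),
                     "threshold": threshold})
    return pd.DataFrame(rows).sort_values(["sex", "biomarker"]
                                          ).reset_index(drop=True)


def adjust_biomarkers(values: pd.DataFrame, flags: pd.DataFrame,
                      factors: pd.DataFrame, statin_at_enrolment: pd.Series,
                      sex: pd.Series) -> pd.DataFrame:
    """Divide flagged biomarkers by the statin factor for on-statin individuals.

    ``values``: iid x biomarker enrolment values.  Only biomarkers flagged for
    the individual's sex, and only individuals on statins at enrolment, are
    modified; everything else is returned unchanged.  Flagged biomarkers must
    have a defined factor.
    """
    adjusted = values.copy()
    flagged = flags[flags["flagged"]]
    fac = factors.set_index(["sex", "biomarker"])["factor"]
    for row in flagged.itertuples(index=False):
        key = (row.sex, row.biomarker)
        if key not in fac.index or not np.isfinite(fac.loc[key]):
            raise ValueError(f"no defined statin factor for {key}")
        if row.biomarker not in adjusted.columns:
            continue
        mask = statin_at_enrolment.reindex(adjusted.index).fillna(False)
        mask &= (sex.reindex(adjusted.index) == row.sex)
        adjusted.loc[mask, row.biomarker] /= fac.loc[key]
    return adjusted


def phewas_biomarkers(prs_z: pd.Series, values: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Linear PheWAS of natural-log biomarkers on the PRS z-score."""
    idx = values.index
    X = pd.concat([prs_z.rename("prs_z").loc[idx], covariates.loc[idx]], axis=1)
    X = sm.add_constant(X, prepend=True)
    rows = []
    for bm in values.columns:
        y = values[bm]
        ok = y.notna()
        if (y[ok] <= 0).any():
            raise ValueError(f"non-positive value for biomarker {bm!r}; "
                             "cannot log transform")
        row = _fit_result_row(bm, "biomarker", "linear", int(ok.sum()))
        fit = sm.OLS(np.log(y[ok].to_numpy()), X[ok.to_numpy()]).fit()
        row.update(estimate=float(fit.params["prs_z"]),
                   se=float(fit.bse["prs_z"]),
                   p=float(fit.pvalues["prs_z"]), converged=True)
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def female_factor_qc(factors: pd.DataFrame) -> pd.DataFrame:
    """Visit selection and range QC for female-specific factors.

    Per individual and factor: the last recorded value is used for parity (live
    births may postdate enrolment), the first recorded value for everything
    else.  Range filters: menarche 8-20, first birth 14-43, menopause 40-63,
    cycle length 22-36 days, first-child birth weight 3-12 lb; parity >= 4
    collapses to a single '4+' category (coded 4).  Returns a wide iid x
    factor frame with NaN where a value was excluded.
    """
    df = factors.sort_values(["iid", "factor", "visit"], kind="mergesort")
    picked = []
    for factor, grp in df.groupby("factor"):
        which = "last" if factor == "parity" else "first"
        sel = grp.drop_duplicates(subset="iid", keep=which)
        picked.append(sel[["iid", "factor", "value"]])
    sel = pd.concat(picked, ignore_index=True)
    wide = sel.pivot(index="iid", columns="factor", values="value")
    for factor, (lo, hi) in FEMALE_FACTOR_RANGES.items():
        if factor in wide.columns:
            v = wide[factor]
            wide[factor] = v.where((v >= lo) & (v <= hi))
    if "parity" in wide.columns:
        wide["parity"] = wide["parity"].clip(upper=4.0)
    wide.columns.name = None
    return wide


def inverse_rank_normal(x: np.ndarray) -> np.ndarray:
    """Blom inverse-rank-normal transform, (rank - 3/8) / (n + 1/4); ties
    share the average rank."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.375) / (len(x) + 0.25))


def _p_from_t(t: float) -> float:
    """Two-sided p from comparing a t-value to a standard normal."""
    return float(2.0 * stats.norm.sf(abs(t)))


def phewas_female_factors(prs_z: pd.Series, factors: pd.DataFrame,
                          covariates: pd.DataFrame,
                          models: dict[str, str] | None = None) -> pd.DataFrame:
    """PheWAS of female-specific factors on the PRS z-score.

    Linear factors are inverse-rank-normal transformed then fit by OLS;
    ordinal factors use a proportional-odds logistic model with p-values from
    the normal tail of the t-value.  Age at menarche is an extra covariate for
    age at first live birth.
    """
    models = dict(FEMALE_FACTOR_MODELS if models is None else models)
    rows = []
    for factor in factors.columns:
        model = models.get(factor, "linear")
        y_all = factors[factor]
        ok = y_all.notna()
        extra = None
        if factor == "first_birth_age" and "menarche_age" in factors.columns:
            extra = factors["menarche_age"]
            ok &= extra.notna()
        idx = factors.index[ok]
        y = y_all.loc[idx]
        X = pd.concat([prs_z.rename("prs_z").loc[idx], covariates.loc[idx]],
                      axis=1)
        if extra is not None:
            X["menarche_age"] = extra.loc[idx]
        row = _fit_result_row(factor, "female-specific", model, len(idx))
        if model == "linear":
            Xc = sm.add_constant(X, prepend=True)
            fit = sm.OLS(inverse_rank_normal(y.to_numpy()), Xc).fit()
            t = float(fit.tvalues["prs_z"])
            row.update(estimate=float(fit.params["prs_z"]),
                       se=float(fit.bse["prs_z"]), p=_p_from_t(t),
                       converged=True)
        else:
            levels = np.unique(y.to_numpy())
            if len(levels) < 2:
                raise ValueError(f"ordinal factor {factor!r} has fewer than "
                                 "two levels after QC")
            codes = pd.Categorical(y, categories=levels, ordered=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mod = OrderedModel(np.asarray(codes.codes), X.to_numpy(),
                                       distr="logit")
                    fit = mod.fit(method="bfgs", maxiter=200, disp=0, gtol=1e-8)
                est = float(fit.params[0])
                se = float(fit.bse[0])
                row.update(estimate=est, se=se, p=_p_from_t(est / se),
                           converged=bool(fit.mle_retvals.get("converged",
                                                              True)))
            except np.linalg.LinAlgError:
                row["note"] = "ordinal fit failed"
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def bonferroni_threshold(alpha: float, n_traits: int) -> float:
    """Per-trait-set Bonferroni significance threshold, alpha / n_traits."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return alpha / n_traits
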