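"""Two-sample Mendelian randomisation.

Instrument selection (genome-wide significance + clumping), exposure/outcome
harmonization, weak-instrument (F) and Steiger directionality filtering, and
the estimator family: per-SNP Wald ratios, inverse-variance weighted (IVW)
with Cochran's Q and multiplicative random-effects SE inflation under
overdispersion, MR-Egger (slope + directional-pleiotropy intercept test),
weighted median with parametric-bootstrap SE, leave-one-out, MR-PRESSO
(simulation-based global, outlier and distortion tests) and multivariable MR.
Benjamini-Hochberg FDR is applied within each (direction x method) group.

The harmonized per-SNP table (:data:`MRINPUT_COLUMNS`) is the common input:
exposure and outcome effects expressed on the same effect allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gwasio import SummaryStats

__all__ = [
    "MRINPUT_COLUMNS",
    "MRResult",
    "select_instruments",
    "harmonize",
    "f_statistics",
    "steiger_filter",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "leave_one_out",
    "mr_presso",
    "mvmr",
    "fdr_within_groups",
    "results_table",
]

MRINPUT_COLUMNS = [
    "snp_id", "eaf",
    "beta_exposure", "se_exposure", "p_exposure", "n_exposure",
    "beta_outcome", "se_outcome", "p_outcome", "n_outcome",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MRResult:
    """One MR estimate: method, effect, uncertainty and diagnostics."""

    method: str
    b: float
    se: float
    p: float
    k: int
    direction: str = "exposure->outcome"
    p_adj: float | None = None
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    outliers: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"method": self.method, "direction": self.direction, "b": self.b,
             "se": self.se, "p": self.p, "p_adj": self.p_adj, "k": self.k,
             "Q": self.Q, "Q_df": self.Q_df, "Q_p": self.Q_p,
             "intercept": self.intercept, "intercept_se": self.intercept_se,
             "intercept_p": self.intercept_p,
             "outliers": ",".join(self.outliers)}
        return d


def results_table(results: list[MRResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _norm_p(z) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def select_instruments(ss: SummaryStats, p_max: float = 5e-8,
                       ld: pd.DataFrame | None = None,
                       distance_bp: float | None = None,
                       r2_clump: float = 0.001) -> SummaryStats:
    """Genome-wide significant, approximately independent instruments.

    SNPs with p strictly below ``p_max`` are clumped greedily in p order:
    each kept SNP removes candidates within 10 Mb at r^2 > ``r2_clump`` when an
    LD matrix (snp x snp r^2 DataFrame) is supplied, otherwise all candidates
    within 1 Mb on the same chromosome (distance-only fallback).
    """
    if distance_bp is None:
        distance_bp = 10e6 if ld is not None else 1e6
    t = ss.table[ss.table["p"] < p_max].copy()
    if t.empty:
        raise ValueError("no instruments reach the significance threshold")
    t = t.sort_values(["p", "snp_id"], kind="mergesort")
    kept_rows = []
    for row in t.itertuples(index=False):
        excluded = False
        for kept in kept_rows:
            same_chr = kept.chrom == row.chrom
            close = same_chr and abs(float(kept.pos) - float(row.pos)) <= distance_bp
            if ld is not None:
                r2 = 0.0
                if (row.snp_id in ld.index) and (kept.snp_id in ld.columns):
                    r2 = float(ld.at[row.snp_id, kept.snp_id])
                if close and r2 > r2_clump:
                    excluded = True
                    break
            elif close:
                excluded = True
                break
        if not excluded:
            kept_rows.append(row)
    out = pd.DataFrame(kept_rows).loc[:, ss.table.columns]
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryStats(ss.trait, ss.cohort, out, ss.lambda_gc)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_eaf_window: tuple[float, float] = (0.42, 0.58)
              ) -> tuple[pd.DataFrame, dict]:
    """Align outcome records to the exposure effect allele.

    Swapped alleles flip the outcome beta (and eaf); strand flips go through
    the base complement.  Palindromic SNPs (A/T, C/G) are resolved by allele
    frequency when both frequencies are informative, and dropped when either
    frequency falls inside ``palindrome_eaf_window`` (ambiguous strand).
    Returns the harmonized per-SNP table and an action-count report.
    """
    exp = exposure.table.set_index("snp_id")
    out = outcome.table.set_index("snp_id")
    shared = exp.index.intersection(out.index)
    report = {"n_shared": int(len(shared)), "flipped": 0, "strand_flipped": 0,
              "dropped_palindromic": 0, "dropped_incompatible": 0,
              "dropped": []}
    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        b_o, eaf_o = o["beta"], o["eaf"]
        if _is_palindromic(ea, oa):
            win_lo, win_hi = palindrome_eaf_window
            eaf_e = e["eaf"]
            ambiguous = (not np.isfinite(eaf_e) or not np.isfinite(eaf_o)
                         or (win_lo < eaf_e < win_hi)
                         or (win_lo < eaf_o < win_hi))
            if ambiguous:
                report["dropped_palindromic"] += 1
                report["dropped"].append(snp)
                continue
            same_side = (eaf_e - 0.5) * (eaf_o - 0.5) > 0
            if not same_side:
                b_o, eaf_o = -b_o, 1.0 - eaf_o
                report["flipped"] += 1
        else:
            o_ea, o_oa = o["effect_allele"], o["other_allele"]
            if (o_ea, o_oa) == (ea, oa):
                pass
            elif (o_oa, o_ea) == (ea, oa):
                b_o, eaf_o = -b_o, 1.0 - eaf_o
                report["flipped"] += 1
            elif (_COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)) == (ea, oa):
                report["strand_flipped"] += 1
            elif (_COMPLEMENT.get(o_oa), _COMPLEMENT.get(o_ea)) == (ea, oa):
                b_o, eaf_o = -b_o, 1.0 - eaf_o
                report["flipped"] += 1
                report["strand_flipped"] += 1
            else:
                report["dropped_incompatible"] += 1
                report["dropped"].append(snp)
                continue
        rows.append({
            "snp_id": snp, "eaf": e["eaf"],
            "beta_exposure": e["beta"], "se_exposure": e["se"],
            "p_exposure": e["p"], "n_exposure": e["n"],
            "beta_outcome": b_o, "se_outcome": o["se"],
            "p_outcome": o["p"], "n_outcome": o["n"],
        })
    mri = pd.DataFrame(rows, columns=MRINPUT_COLUMNS)
    return mri, report


def f_statistics(mri: pd.DataFrame, f_min: float = 10.0
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-SNP instrument strength F = (beta/se)^2; drop F <= f_min."""
    F = (mri["beta_exposure"] / mri["se_exposure"]) ** 2
    F.name = "F"
    keep = F > f_min
    return mri[keep].reset_index(drop=True), F


def steiger_filter(mri: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain SNPs explaining more variance in the exposure than the outcome.

    Variance explained is approximated from the test statistic and sample
    size, r^2 = z^2 / (z^2 + n - 2); retention requires strictly greater
    exposure r^2.
    """
    if (mri["n_exposure"] <= 2).any() or (mri["n_outcome"] <= 2).any():
        raise ValueError("Steiger filter needs per-SNP n > 2 for both traits")
    z_e = mri["beta_exposure"] / mri["se_exposure"]
    z_o = mri["beta_outcome"] / mri["se_outcome"]
    r2_e = z_e ** 2 / (z_e ** 2 + mri["n_exposure"] - 2.0)
    r2_o = z_o ** 2 / (z_o ** 2 + mri["n_outcome"] - 2.0)
    r2 = pd.DataFrame({"snp_id": mri["snp_id"], "r2_exposure": r2_e,
                       "r2_outcome": r2_o,
                       "retained": (r2_e > r2_o).to_numpy()})
    return mri[r2["retained"].to_numpy()].reset_index(drop=True), r2


def wald_ratio(record: pd.Series, direction: str = "exposure->outcome"
               ) -> MRResult:
    """Single-SNP causal estimate b = beta_Y / beta_X with first-order SE."""
    bx, by = float(record["beta_exposure"]), float(record["beta_outcome"])
    sy = float(record["se_outcome"])
    if bx == 0:
        raise ValueError("Wald ratio undefined for beta_exposure = 0")
    b = by / bx
    se = abs(sy / bx)
    return MRResult("wald", b, se, float(_norm_p(b / se)), 1, direction)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray
              ) -> tuple[float, float, float]:
    """Fixed-effect IVW point estimate, fixed SE and Cochran's Q."""
    w = 1.0 / sy ** 2
    den = float(np.sum(w * bx * bx))
    b = float(np.sum(w * bx * by)) / den
    se_fixed = den ** -0.5
    Q = float(np.sum(w * (by - b * bx) ** 2))
    return b, se_fixed, Q


def ivw(mri: pd.DataFrame, direction: str = "exposure->outcome") -> MRResult:
    """Inverse-variance weighted estimate with heterogeneity statistics.

    Fixed-effect weighting by 1/se_outcome^2; when Cochran's Q exceeds its
    degrees of freedom the SE is inflated multiplicatively by sqrt(Q/(k-1))
    (multiplicative random-effects model), so overdispersion widens the CI
    without reweighting.
    """
    k = len(mri)
    if k < 1:
        raise ValueError("IVW needs at least one SNP")
    bx = mri["beta_exposure"].to_numpy(dtype=float)
    by = mri["beta_outcome"].to_numpy(dtype=float)
    sy = mri["se_outcome"].to_numpy(dtype=float)
    if k == 1:
        # exact reduction to the single-SNP Wald ratio
        b, se = by[0] / bx[0], abs(sy[0] / bx[0])
        return MRResult("ivw", float(b), float(se), float(_norm_p(b / se)),
                        1, direction, Q=0.0, Q_df=0, Q_p=1.0)
    b, se, Q = _ivw_core(bx, by, sy)
    Q_df = k - 1
    if Q_df > 0 and Q / Q_df > 1.0:
        se *= math.sqrt(Q / Q_df)
    Q_p = float(stats.chi2.sf(Q, Q_df)) if Q_df > 0 else 1.0
    return MRResult("ivw", b, se, float(_norm_p(b / se)), k, direction,
                    Q=Q, Q_df=Q_df, Q_p=Q_p)


def mr_egger(mri: pd.DataFrame, direction: str = "exposure->outcome"
             ) -> MRResult:
    """MR-Egger: weighted regression with intercept for directional pleiotropy.

    SNPs are oriented to positive exposure effects (both betas flipped),
    weights are 1/se_outcome^2; the slope is the causal estimate and the
    intercept's departure from zero tests directional pleiotropy.  SEs use the
    residual scale floored at 1 and p-values come from a t distribution with
    k - 2 degrees of freedom.
    """
    k = len(mri)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    sign = np.sign(mri["beta_exposure"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    bx = mri["beta_exposure"].to_numpy(dtype=float) * sign
    by = mri["beta_outcome"].to_numpy(dtype=float) * sign
    sy = mri["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx_inv = np.linalg.inv(X.T @ WX)
    coef = xtwx_inv @ (WX.T @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2) / (k - 2))
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(xtwx_inv) * scale)
    t_slope = coef[1] / ses[1]
    t_int = coef[0] / ses[0]
    p_slope = float(2.0 * stats.t.sf(abs(t_slope), k - 2))
    p_int = float(2.0 * stats.t.sf(abs(t_int), k - 2))
    return MRResult("egger", float(coef[1]), float(ses[1]), p_slope, k,
                    direction, intercept=float(coef[0]),
                    intercept_se=float(ses[0]), intercept_p=p_int)


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5))  # first index with cum >= 0.5
    lo, hi = j - 1, j
    frac = (0.5 - cum[lo]) / (cum[hi] - cum[lo])
    return float(r[lo] + frac * (r[hi] - r[lo]))


def weighted_median(mri: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                    direction: str = "exposure->outcome") -> MRResult:
    """Weighted-median estimator; valid if >= 50% of weight is from valid IVs.

    Per-SNP Wald ratios are ordered and the estimate interpolates the ratio at
    cumulative weight 0.5, with inverse-variance ratio weights.  The SE is a
    seeded parametric bootstrap over the per-SNP exposure and outcome betas.
    """
    k = len(mri)
    if k < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    bx = mri["beta_exposure"].to_numpy(dtype=float)
    by = mri["beta_outcome"].to_numpy(dtype=float)
    sx = mri["se_exposure"].to_numpy(dtype=float)
    sy = mri["se_outcome"].to_numpy(dtype=float)
    ratios = by / bx
    var_ratio = sy ** 2 / bx ** 2 + (by ** 2 * sx ** 2) / bx ** 4
    weights = 1.0 / var_ratio
    b = _weighted_median_estimate(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_s = bx + sx * rng.standard_normal(k)
        by_s = by + sy * rng.standard_normal(k)
        r_s = by_s / bx_s
        v_s = sy ** 2 / bx_s ** 2 + (by_s ** 2 * sx ** 2) / bx_s ** 4
        boots[i] = _weighted_median_estimate(r_s, 1.0 / v_s)
    se = float(boots.std())
    return MRResult("weighted_median", b, se, float(_norm_p(b / se)), k,
                    direction)


def leave_one_out(mri: pd.DataFrame, alpha: float = 0.05,
                  direction: str = "exposure->outcome") -> pd.DataFrame:
    """IVW estimates each omitting one SNP; flags verdict-changing omissions."""
    k = len(mri)
    if k < 2:
        raise ValueError("leave-one-out needs at least 2 SNPs")
    full = ivw(mri, direction)
    rows = []
    for i in range(k):
        sub = mri.drop(mri.index[i])
        if len(sub) == 1:
            r = wald_ratio(sub.iloc[0], direction)
        else:
            r = ivw(sub, direction)
        rows.append({"omitted": mri["snp_id"].iloc[i], "b": r.b, "se": r.se,
                     "p": r.p, "k": r.k,
                     "verdict_change": (r.p < alpha) != (full.p < alpha)})
    return pd.DataFrame(rows)


def mr_presso(mri: pd.DataFrame, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0, direction: str = "exposure->outcome"
              ) -> tuple[MRResult, MRResult, dict]:
    """MR-PRESSO: residual-sum-of-squares global test, outlier removal,
    distortion test.

    Each SNP's residual is taken against the leave-one-out IVW prediction;
    the observed weighted RSS is compared to ``n_sim`` parametric simulations
    under the fitted model (global test).  Per-SNP squared residuals give
    outlier p-values, Bonferroni-corrected over k.  Outliers are removed and
    IVW refit (the outlier-adjusted estimate equals the raw IVW when none are
    found).  The distortion test compares the raw-vs-adjusted shift to the
    shift from removing random same-size SNP subsets.
    """
    k = len(mri)
    if k < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    bx = mri["beta_exposure"].to_numpy(dtype=float)
    by = mri["beta_outcome"].to_numpy(dtype=float)
    sx = mri["se_exposure"].to_numpy(dtype=float)
    sy = mri["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy ** 2

    def _loo_b(bxa, bya):
        S1 = np.sum(w * bxa * bya, axis=-1, keepdims=True)
        S2 = np.sum(w * bxa * bxa, axis=-1, keepdims=True)
        return (S1 - w * bxa * bya) / (S2 - w * bxa * bxa)

    b_loo = _loo_b(bx, by)
    res_obs = by - b_loo * bx
    rss_obs = float(np.sum(w * res_obs ** 2))

    # parametric simulations under the leave-one-out fitted model
    bx_sim = bx + sx * rng.standard_normal((n_sim, k))
    by_sim = b_loo * bx_sim + sy * rng.standard_normal((n_sim, k))
    b_loo_sim = _loo_b(bx_sim, by_sim)
    res_sim = by_sim - b_loo_sim * bx_sim
    rss_sim = np.sum(w * res_sim ** 2, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    sq_obs = w * res_obs ** 2
    sq_sim = w * res_sim ** 2
    outlier_p = (1 + np.sum(sq_sim >= sq_obs, axis=0)) / (n_sim + 1)
    is_outlier = outlier_p < (outlier_alpha / k)
    outlier_snps = list(mri["snp_id"].to_numpy()[is_outlier])

    raw = ivw(mri, direction)
    raw.method = "mr_presso_raw"
    raw.extra["global_p"] = global_p
    if is_outlier.any() and (~is_outlier).sum() >= 1:
        sub = mri[~is_outlier].reset_index(drop=True)
        adjusted = (ivw(sub, direction) if len(sub) > 1
                    else wald_ratio(sub.iloc[0], direction))
    else:
        adjusted = ivw(mri, direction)
    adjusted.method = "mr_presso_outlier_adjusted"
    adjusted.outliers = outlier_snps

    distortion: dict = {"n_outliers": int(is_outlier.sum()),
                        "coefficient": np.nan, "p": np.nan}
    n_out = int(is_outlier.sum())
    if 0 < n_out < k:
        d_obs = raw.b - adjusted.b
        inlier_idx = np.flatnonzero(~is_outlier)
        sims = np.empty(min(n_sim, 500))
        for i in range(len(sims)):
            drop = rng.choice(inlier_idx, size=n_out, replace=False)
            keep = np.setdiff1d(np.arange(k), drop)
            b_sub, _, _ = _ivw_core(bx[keep], by[keep], sy[keep])
            sims[i] = raw.b - b_sub
        denom = adjusted.b if adjusted.b != 0 else np.nan
        distortion["coefficient"] = float(100.0 * d_obs / denom)
        distortion["p"] = float((1 + np.sum(np.abs(sims) >= abs(d_obs)))
                                / (len(sims) + 1))
    report = {"global_rss": rss_obs, "global_p": global_p,
              "outliers": outlier_snps,
              "outlier_p": dict(zip(mri["snp_id"], outlier_p)),
              "distortion": distortion}
    return raw, adjusted, report


def mvmr(mri: pd.DataFrame, exposure_names: list[str],
         direction: str = "exposure->outcome") -> list[MRResult]:
    """Multivariable MR: conditional causal estimate per exposure.

    ``mri`` carries one ``beta_<name>``/``se_<name>`` column pair per exposure
    plus the outcome columns; the outcome betas are regressed on the
    exposure-beta matrix without intercept, weighted by 1/se_outcome^2.
    """
    k = len(mri)
    cols = [f"beta_{name}" for name in exposure_names]
    X = mri[cols].to_numpy(dtype=float)
    if k < X.shape[1]:
        raise ValueError("fewer SNPs than exposures")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending exposures: columns linearly dependent on earlier ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, :j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(exposure_names[j])
        raise ValueError(f"exposure-beta matrix rank-deficient; collinear "
                         f"exposure(s): {bad or exposure_names}")
    by = mri["beta_outcome"].to_numpy(dtype=float)
    sy = mri["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy ** 2
    WX = X * w[:, None]
    xtwx_inv = np.linalg.inv(X.T @ WX)
    coef = xtwx_inv @ (WX.T @ by)
    dof = k - X.shape[1]
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2) / dof) if dof > 0 else 1.0
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(xtwx_inv) * scale)
    out = []
    for name, b, se in zip(exposure_names, coef, ses):
        p = float(2.0 * stats.t.sf(abs(b / se), dof)) if dof > 0 else 1.0
        r = MRResult("mvmr", float(b), float(se), p, k, direction)
        r.extra["exposure"] = name
        out.append(r)
    return out


def fdr_within_groups(results: pd.DataFrame, p_col: str = "p",
                      group_cols: tuple[str, ...] = ("direction", "method")
                      ) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted p-values within each (direction x method)
    group; adjusted p is monotone nondecreasing in raw p within a group."""
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(list(group_cols)).groups.items():
        p = out.loc[idx, p_col].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if ok.sum() == 0:
            continue
        adj = multipletests(p[ok], method="fdr_bh")[1]
        vals = np.full(len(p), np.nan)
        vals[ok] = adj
        out.loc[idx, "p_adj"] = vals
    return out
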