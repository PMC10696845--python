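"""GWAS summary-statistics I/O, quality control and fixed-effect meta-analysis.

The unit of work is :class:`SummaryStats`: one trait's per-variant association
records (rsID, alleles, frequency, beta, SE, p, N) held in a pandas DataFrame
with canonical column names.  Files are tab-delimited with configurable column
aliases, since public GWAS downloads disagree on header conventions; gzip is
handled transparently by extension.

Also hosts the phecode machinery: reading the ICD10->phecode map and phecode
definition CSVs in the PheWAS-catalog layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FormatError",
    "QCError",
    "SummaryStats",
    "PhecodeMap",
    "SUMSTATS_COLUMNS",
    "DEFAULT_ALIASES",
    "read_sumstats",
    "write_sumstats",
    "qc_sumstats",
    "genomic_control",
    "meta_fixed",
    "read_phecode_map",
]

#: canonical column order for summary-statistics tables
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

_NUMERIC_COLUMNS = ["pos", "eaf", "beta", "se", "p", "n"]

#: header aliases for the common summary-statistics dialects (case-insensitive)
DEFAULT_ALIASES: dict[str, list[str]] = {
    "snp_id": ["snp_id", "snp", "rsid", "rs_id", "markername", "id", "variant_id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "ea", "allele1", "alt"],
    "other_allele": ["other_allele", "a2", "oa", "nea", "allele2", "ref",
                     "non_effect_allele"],
    "eaf": ["eaf", "freq", "af", "frq", "effect_allele_frequency", "maf", "freq1"],
    "beta": ["beta", "b", "effect", "es"],
    "se": ["se", "stderr", "standard_error", "sebeta"],
    "p": ["p", "pval", "p_value", "pvalue", "p-value"],
    "n": ["n", "samplesize", "sample_size", "neff"],
}

# median of the 1-df chi-square; denominator of the genomic-control lambda
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


class QCError(ValueError):
    """Raised when quality control cannot be completed as requested."""


@dataclass
class SummaryStats:
    """Per-variant association records for a single trait and cohort."""

    trait: str
    cohort: str
    table: pd.DataFrame
    lambda_gc: float | None = None
    read_report: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary statistics missing columns: {missing}")
        self.table = self.table.loc[:, SUMSTATS_COLUMNS].reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def copy(self) -> "SummaryStats":
        return SummaryStats(self.trait, self.cohort, self.table.copy(),
                            self.lambda_gc, dict(self.read_report))

    def validate(self) -> None:
        """Check the record-level invariants (SE > 0, p in (0,1], allele codes)."""
        t = self.table
        if (t["se"] <= 0).any():
            raise QCError("non-positive SE present")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise QCError("p outside (0, 1] present")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise QCError("identical effect/other alleles present")
        eaf = t["eaf"].dropna()
        if ((eaf < 0) | (eaf > 1)).any():
            raise QCError("eaf outside [0, 1] present")


def _resolve_columns(header: list[str], column_spec: dict | None) -> dict[str, str]:
    """Map canonical field names to file column names via the alias table."""
    aliases = {k: [a.lower() for a in v] for k, v in DEFAULT_ALIASES.items()}
    if column_spec:
        for key, name in column_spec.items():
            aliases[key] = [str(name).lower()]
    lower = [h.lower() for h in header]
    if len(set(lower)) != len(lower):
        dupes = sorted({h for h in lower if lower.count(h) > 1})
        raise FormatError(f"duplicated header column(s): {dupes}")
    resolved: dict[str, str] = {}
    for key in SUMSTATS_COLUMNS:
        for cand in aliases[key]:
            if cand in lower:
                resolved[key] = header[lower.index(cand)]
                break
    required = [c for c in SUMSTATS_COLUMNS if c not in ("eaf", "n", "chrom", "pos")]
    missing = [c for c in required if c not in resolved]
    if missing:
        raise FormatError(f"could not resolve required column(s): {missing}")
    return resolved


def read_sumstats(path, column_spec: dict | None = None, trait: str = "trait",
                  cohort: str = "cohort") -> SummaryStats:
    """Read tab-delimited summary statistics.

    ``column_spec`` maps canonical names (keys of :data:`DEFAULT_ALIASES`) to
    exact file column names, overriding the alias search.  Rows whose numeric
    fields fail to parse are dropped; their 1-based data line numbers are
    recorded in ``read_report["bad_lines"]``.
    """
    # inspect the raw header ourselves: pandas silently renames duplicates
    raw_header = pd.read_csv(path, sep="\t", header=None, nrows=1,
                             dtype=str).iloc[0].tolist()
    raw = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(raw_header, column_spec)
    df = pd.DataFrame(index=raw.index)
    for key in SUMSTATS_COLUMNS:
        df[key] = raw[resolved[key]] if key in resolved else np.nan
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # required numeric fields that were present as text but failed to parse
    bad = pd.Series(False, index=df.index)
    for col in ("beta", "se", "p"):
        raw_col = raw[resolved[col]]
        bad |= df[col].isna() & raw_col.notna() & (raw_col.str.strip() != "")
    bad |= df["beta"].isna() | df["se"].isna() | df["p"].isna()
    bad_lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
    df = df[~bad].reset_index(drop=True)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    df["chrom"] = df["chrom"].astype(str).where(df["chrom"].notna(), None)
    report = {"n_read": int(len(raw)), "n_kept": int(len(df)),
              "bad_lines": bad_lines}
    return SummaryStats(trait=trait, cohort=cohort, table=df, read_report=report)


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write canonical tab-delimited summary statistics (NA for missing)."""
    ss.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def _align_eaf(row_ea, row_oa, ref_ea, ref_oa, ref_eaf):
    """Return the reference eaf expressed on ``row_ea``; NaN if irreconcilable."""
    pairs = [
        (ref_ea, ref_oa, ref_eaf),
        (ref_oa, ref_ea, 1.0 - ref_eaf),
        (_COMPLEMENT.get(ref_ea, "?"), _COMPLEMENT.get(ref_oa, "?"), ref_eaf),
        (_COMPLEMENT.get(ref_oa, "?"), _COMPLEMENT.get(ref_ea, "?"), 1.0 - ref_eaf),
    ]
    for ea, oa, eaf in pairs:
        if ea == row_ea and oa == row_oa:
            return eaf
    return np.nan


def qc_sumstats(ss: SummaryStats, reference: SummaryStats | None = None,
                total_n: float | None = None) -> tuple[SummaryStats, dict]:
    """Quality-control one trait's summary statistics.

    Actions (each counted in the returned report): rows with missing beta/SE or
    p outside (0, 1] removed; missing per-SNP N filled with ``total_n``;
    duplicated rsIDs resolved keeping the lowest p; missing allele frequencies
    filled from ``reference`` by rsID with allele alignment.  Output is sorted
    by (chrom, pos).
    """
    t = ss.table.copy()
    report: dict[str, int] = {}
    n0 = len(t)
    t = t[t["beta"].notna() & t["se"].notna() & t["p"].notna() & (t["se"] > 0)]
    report["removed_missing_or_bad_se"] = n0 - len(t)

    n0 = len(t)
    t = t[(t["p"] > 0) & (t["p"] <= 1)]
    report["removed_p_out_of_range"] = n0 - len(t)

    n_missing_n = int(t["n"].isna().sum())
    if n_missing_n and total_n is not None:
        t.loc[t["n"].isna(), "n"] = float(total_n)
        report["n_filled_with_total"] = n_missing_n
    else:
        report["n_filled_with_total"] = 0

    n0 = len(t)
    t = t.sort_values("p", kind="mergesort").drop_duplicates("snp_id", keep="first")
    report["duplicates_removed"] = n0 - len(t)

    need_eaf = t["eaf"].isna()
    report["eaf_filled_from_reference"] = 0
    if need_eaf.any():
        if reference is None:
            raise QCError("allele frequencies missing and no reference supplied")
        ref = reference.table.set_index("snp_id")
        filled = 0
        for idx in t.index[need_eaf]:
            rsid = t.at[idx, "snp_id"]
            if rsid in ref.index:
                r = ref.loc[rsid]
                eaf = _align_eaf(t.at[idx, "effect_allele"],
                                 t.at[idx, "other_allele"],
                                 r["effect_allele"], r["other_allele"], r["eaf"])
                if not math.isnan(eaf):
                    t.at[idx, "eaf"] = eaf
                    filled += 1
        report["eaf_filled_from_reference"] = filled

    t = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out = SummaryStats(ss.trait, ss.cohort, t, ss.lambda_gc)
    return out, report


def genomic_control(ss: SummaryStats) -> SummaryStats:
    """Apply genomic control: deflate test statistics by the median inflation.

    lambda = median((beta/se)^2) / 0.4549...; when lambda > 1, SEs are inflated
    by sqrt(lambda) and p recomputed from the corrected z.  lambda <= 1 leaves
    the table unchanged (no deflation of well-calibrated statistics).
    """
    if ss.n_variants < 1:
        raise QCError("genomic control needs at least one variant")
    t = ss.table.copy()
    z2 = (t["beta"] / t["se"]) ** 2
    lam = float(np.median(z2) / _CHI2_MEDIAN)
    if lam > 1.0:
        t["se"] = t["se"] * math.sqrt(lam)
        z = t["beta"] / t["se"]
        t["p"] = 2.0 * stats.norm.sf(np.abs(z))
        t.loc[t["p"] > 1.0, "p"] = 1.0
    return SummaryStats(ss.trait, ss.cohort, t, lambda_gc=lam)


def _orient_to(beta, eaf, ea, oa, target_ea, target_oa):
    """Express (beta, eaf, alleles) on the target allele pair; None if impossible."""
    if (ea, oa) == (target_ea, target_oa):
        return beta, eaf
    if (oa, ea) == (target_ea, target_oa):
        return -beta, (1.0 - eaf) if eaf == eaf else np.nan
    cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
    if (cea, coa) == (target_ea, target_oa):
        return beta, eaf
    if (coa, cea) == (target_ea, target_oa):
        return -beta, (1.0 - eaf) if eaf == eaf else np.nan
    return None


def meta_fixed(cohorts: list[SummaryStats], apply_gc: bool = False,
               trait: str | None = None) -> tuple[SummaryStats, dict]:
    """Fixed-effect inverse-variance meta-analysis across cohorts.

    Per SNP: beta = sum(b_i/se_i^2)/sum(1/se_i^2), se = sum(1/se_i^2)^(-1/2),
    p from the normal z; N is the sum over the cohorts the SNP is present in.
    When ``apply_gc`` is set, per-cohort genomic control runs first.  Alleles
    are harmonized to the record from the largest-n cohort carrying the SNP
    (ties broken by cohort label), so the result is invariant to cohort order.
    SNPs with irreconcilable alleles in any cohort are dropped and reported.
    """
    if not cohorts:
        raise QCError("meta-analysis needs at least one cohort")
    if apply_gc:
        cohorts = [genomic_control(c) for c in cohorts]
    lambdas = {c.cohort: c.lambda_gc for c in cohorts}

    # collect per-SNP contributions
    per_snp: dict[str, list] = {}
    for c in cohorts:
        for row in c.table.itertuples(index=False):
            per_snp.setdefault(row.snp_id, []).append((c.cohort, row))

    dropped: list[str] = []
    out_rows = []
    for snp_id, entries in per_snp.items():
        # anchor: largest n (missing n sorts last), tie -> smaller cohort label
        def _key(e):
            n = e[1].n
            return (-(n if n == n and n is not None else -math.inf), e[0])
        anchor = min(entries, key=_key)[1]
        num = den = n_sum = 0.0
        eaf_num = eaf_den = 0.0
        ok = True
        for _, row in entries:
            oriented = _orient_to(row.beta, row.eaf, row.effect_allele,
                                  row.other_allele, anchor.effect_allele,
                                  anchor.other_allele)
            if oriented is None:
                ok = False
                break
            beta, eaf = oriented
            w = 1.0 / row.se ** 2
            num += w * beta
            den += w
            n_i = row.n if row.n == row.n and row.n is not None else 0.0
            n_sum += n_i
            if eaf == eaf:
                wn = n_i if n_i > 0 else 1.0
                eaf_num += wn * eaf
                eaf_den += wn
        if not ok:
            dropped.append(snp_id)
            continue
        beta = num / den
        se = den ** -0.5
        p = min(1.0, 2.0 * stats.norm.sf(abs(beta / se)))
        out_rows.append({
            "snp_id": snp_id, "chrom": anchor.chrom, "pos": anchor.pos,
            "effect_allele": anchor.effect_allele,
            "other_allele": anchor.other_allele,
            "eaf": eaf_num / eaf_den if eaf_den > 0 else np.nan,
            "beta": beta, "se": se, "p": p,
            "n": n_sum if n_sum > 0 else np.nan,
        })
    table = pd.DataFrame(out_rows, columns=SUMSTATS_COLUMNS)
    table = table.sort_values(["chrom", "pos", "snp_id"],
                              kind="mergesort").reset_index(drop=True)
    report = {"snps_dropped_alleles": dropped, "lambda_gc": lambdas,
              "n_cohorts": len(cohorts)}
    meta = SummaryStats(trait or cohorts[0].trait, "meta", table)
    return meta, report


# ---------------------------------------------------------------------------
# phecode maps


@dataclass
class PhecodeMap:
    """ICD10 -> phecode mapping plus phecode definitions (description, category)."""

    icd_to_phecode: dict[str, str]
    definitions: pd.DataFrame  # columns: phecode, description, category

    def lookup(self, icd10: str) -> str | None:
        return self.icd_to_phecode.get(icd10)

    def codes_for(self, phecode: str) -> list[str]:
        return sorted(c for c, p in self.icd_to_phecode.items() if p == phecode)

    def category(self, phecode: str) -> str:
        d = self.definitions.set_index("phecode")
        return str(d.at[phecode, "category"])

    @property
    def phecodes(self) -> list[str]:
        return sorted(set(self.icd_to_phecode.values()), key=float)


def _find_col(columns, needles):
    lower = {c.lower().replace(" ", "").replace("_", ""): c for c in columns}
    for needle in needles:
        if needle in lower:
            return lower[needle]
    raise FormatError(f"no column matching any of {needles} in {list(columns)}")


def read_phecode_map(icd_map_path, definitions_path) -> PhecodeMap:
    """Read the PheWAS-catalog style ICD10 map and phecode definition CSVs.

    Where an ICD10 code maps to multiple phecodes, the numerically smallest
    phecode is kept (deterministic resolution of multi-mapped codes).  Every
    mapped phecode must carry a definition entry with a category.
    """
    icd = pd.read_csv(icd_map_path, dtype=str)
    if icd.empty:
        raise FormatError("empty ICD10->phecode map")
    icd_col = _find_col(icd.columns, ["icd10", "icd10code", "code"])
    phe_col = _find_col(icd.columns, ["phecode"])
    icd = icd[[icd_col, phe_col]].dropna()
    icd.columns = ["icd10", "phecode"]
    icd["_num"] = icd["phecode"].astype(float)
    icd = icd.sort_values(["icd10", "_num"], kind="mergesort")
    icd = icd.drop_duplicates("icd10", keep="first")
    mapping = dict(zip(icd["icd10"], icd["phecode"]))

    defs = pd.read_csv(definitions_path, dtype=str)
    if defs.empty:
        raise FormatError("empty phecode definitions")
    p_col = _find_col(defs.columns, ["phecode"])
    d_col = _find_col(defs.columns, ["phenotype", "description"])
    c_col = _find_col(defs.columns, ["category"])
    defs = defs[[p_col, d_col, c_col]]
    defs.columns = ["phecode", "description", "category"]
    defs = defs.drop_duplicates("phecode").reset_index(drop=True)
    defined = set(defs["phecode"])
    undefined = sorted(set(mapping.values()) - defined, key=float)
    if undefined:
        raise FormatError(f"phecodes without definition entry: {undefined}")
    if defs["category"].isna().any():
        raise FormatError("phecode definition with missing category")
    return PhecodeMap(mapping, defs)
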