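"""Genotype QC, LD pruning, PCA covariates and plink-style PRS scoring.

Dosages live in a dense individuals x variants float matrix with NaN for
missing calls; variant metadata (rsID, position, counted allele, frequency)
travels alongside in a DataFrame.  The operations mirror the plink toolchain:
Hardy-Weinberg exact filtering, MAF/missingness filters, sliding-window LD
pruning, PCA on standardized genotypes and ``--score``-semantics risk scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "hwe_exact_test",
    "variant_qc",
    "ld_prune",
    "pca_covariates",
    "prs_score",
    "zscore",
    "read_weights",
    "write_weights",
    "write_dosages",
    "read_dosages",
    "read_vcf_genotypes",
]

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "counted_allele", "other_allele", "freq"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages[i, j]`` counts copies of the counted allele of variant ``j`` in
    individual ``i`` (0/1/2, NaN for missing).  ``variants.freq`` is the
    counted-allele frequency.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape inconsistent with metadata")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(list(self.samples),
                              self.variants.iloc[idx].reset_index(drop=True),
                              self.dosages[:, idx].copy())

    def observed_freq(self) -> np.ndarray:
        """Counted-allele frequency from non-missing dosages, per variant."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, heterozygote counts of the same
    parity are enumerated; p is the total probability of configurations no more
    likely than the observed one.  Returns p in (0, 1].
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("HWE test undefined for empty sample")
    rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    # unnormalized log-probability of each heterozygote count
    logp = (hets * math.log(2.0)
            - gammaln(n_rare_hom + 1) - gammaln(hets + 1)
            - gammaln(n_common_hom + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_het)[0]]
    p = float(prob[prob <= obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def variant_qc(G: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.05,
               hwe_p_min: float = 1e-6) -> tuple[GenotypeMatrix, dict]:
    """Filter variants on MAF (> maf_min), missingness (< miss_max) and HWE.

    A variant passes HWE when its exact-test p-value is >= ``hwe_p_min``.
    Returns the filtered matrix and per-filter removal counts.
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    freq = G.observed_freq()
    maf = np.minimum(freq, 1.0 - freq)
    miss = np.mean(np.isnan(G.dosages), axis=0)
    fail_maf = ~(maf > maf_min)
    fail_miss = ~(miss < miss_max)
    fail_hwe = np.zeros(G.n_variants, dtype=bool)
    for j in range(G.n_variants):
        d = G.dosages[:, j]
        d = d[~np.isnan(d)]
        counts = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        if sum(counts) == 0:
            fail_hwe[j] = True
            continue
        fail_hwe[j] = hwe_exact_test(*counts) < hwe_p_min
    keep = ~(fail_maf | fail_miss | fail_hwe)
    report = {
        "n_input": int(G.n_variants),
        "removed_maf": int(fail_maf.sum()),
        "removed_missingness": int(fail_miss.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "n_kept": int(keep.sum()),
    }
    return G.subset_variants(keep), report


def _imputed_centered(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and center columns."""
    col_mean = np.nanmean(dosages, axis=0)
    X = np.where(np.isnan(dosages), col_mean, dosages)
    return X - col_mean


def ld_prune(G: GenotypeMatrix, window_kb: float = 50, step: int = 5,
             r2_max: float = 0.2) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained snp_ids.

    Within each window (variants within ``window_kb`` of the window's first
    variant, same chromosome) any retained pair with squared dosage correlation
    above ``r2_max`` is broken by removing the lower-MAF member (ties: the
    later-position member).  The window start advances by ``step`` variants.
    """
    v = G.variants
    keep = np.ones(G.n_variants, dtype=bool)
    freq = G.observed_freq()
    maf = np.minimum(freq, 1.0 - freq)
    X = _imputed_centered(G.dosages)
    sd = X.std(axis=0)

    for chrom in pd.unique(v["chrom"]):
        idx = np.flatnonzero((v["chrom"] == chrom).to_numpy())
        pos = v["pos"].to_numpy()[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"variants not position-sorted on chromosome {chrom}")
        start = 0
        while start < len(idx):
            in_win = np.flatnonzero(
                (pos >= pos[start]) & (pos <= pos[start] + window_kb * 1000.0))
            win = [idx[i] for i in in_win if keep[idx[i]]]
            changed = True
            while changed and len(win) > 1:
                changed = False
                for a_i in range(len(win)):
                    for b_i in range(a_i + 1, len(win)):
                        a, b = win[a_i], win[b_i]
                        if sd[a] == 0 or sd[b] == 0:
                            r2 = 1.0 if sd[a] == sd[b] else 0.0
                        else:
                            r = float(X[:, a] @ X[:, b]) / (len(X) * sd[a] * sd[b])
                            r2 = r * r
                        if r2 > r2_max:
                            # remove lower MAF; tie -> later position
                            if maf[a] < maf[b]:
                                drop = a
                            elif maf[b] < maf[a]:
                                drop = b
                            else:
                                drop = b if v.at[b, "pos"] >= v.at[a, "pos"] else a
                            keep[drop] = False
                            win.remove(drop)
                            changed = True
                            break
                    if changed:
                        break
            start += step
    return list(v.loc[keep, "snp_id"])


def pca_covariates(G: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal-component scores of the standardized genotype matrix.

    Genotypes are mean-imputed and standardized per SNP by sqrt(2p(1-p)); the
    scores are the top-k left singular vectors scaled by their singular values.
    The sign of each component is fixed so its largest-magnitude SNP loading is
    positive.
    """
    if k == 0:
        return pd.DataFrame(index=pd.Index(G.samples, name="iid"))
    Xc = _imputed_centered(G.dosages)
    p = np.nanmean(G.dosages, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = denom > 0
    Xs = Xc[:, ok] / denom[ok]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    tol = S.max() * max(Xs.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if k > rank:
        raise ValueError(f"requested k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=pd.Index(G.samples, name="iid"), columns=cols)


def prs_score(G: GenotypeMatrix, weights: pd.DataFrame,
              average: bool = True) -> tuple[pd.Series, dict]:
    """Polygenic score with plink ``--score`` semantics.

    ``weights`` columns: snp_id, effect_allele, weight.  If the matrix's
    counted allele differs from the weight's effect allele the dosage is
    flipped (2 - dosage); missing dosages are imputed at twice the effect
    allele frequency; by default the score is the weighted-dosage average over
    2 x (number of matched SNPs).
    """
    if weights["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_ids in weight table")
    meta = G.variants.set_index("snp_id")
    total = np.zeros(G.n_samples)
    matched = 0
    unmatched: list[str] = []
    for row in weights.itertuples(index=False):
        if row.snp_id not in meta.index:
            unmatched.append(row.snp_id)
            continue
        j = meta.index.get_loc(row.snp_id)
        counted = meta.at[row.snp_id, "counted_allele"]
        other = meta.at[row.snp_id, "other_allele"]
        freq = meta.at[row.snp_id, "freq"]
        dose = G.dosages[:, j].copy()
        if row.effect_allele == counted:
            eaf = freq
        elif row.effect_allele == other:
            dose = 2.0 - dose
            eaf = 1.0 - freq
        else:
            unmatched.append(row.snp_id)
            continue
        dose = np.where(np.isnan(dose), 2.0 * eaf, dose)
        total += row.weight * dose
        matched += 1
    if matched == 0:
        raise ValueError("no weight SNPs overlap the genotype matrix")
    score = total / (2.0 * matched) if average else total
    report = {"n_matched": matched, "unmatched": unmatched}
    return pd.Series(score, index=pd.Index(G.samples, name="iid"),
                     name="prs"), report


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 within the supplied cohort."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# file formats


def write_weights(weights: pd.DataFrame, path) -> None:
    weights[["snp_id", "effect_allele", "weight"]].to_csv(
        path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "effect_allele": str})
    need = {"snp_id", "effect_allele", "weight"}
    if not need.issubset(w.columns):
        raise ValueError(f"weight table must have columns {sorted(need)}")
    return w


def write_dosages(G: GenotypeMatrix, path) -> None:
    """TSV dosage matrix with a ``##VAR`` metadata header block."""
    with open(path, "w") as fh:
        for row in G.variants.itertuples(index=False):
            fh.write(f"##VAR\t{row.snp_id}\t{row.chrom}\t{row.pos}"
                     f"\t{row.counted_allele}\t{row.other_allele}\t{row.freq}\n")
        fh.write("iid\t" + "\t".join(G.variants["snp_id"]) + "\n")
        for i, iid in enumerate(G.samples):
            vals = ["NA" if np.isnan(d) else f"{d:g}" for d in G.dosages[i]]
            fh.write(iid + "\t" + "\t".join(vals) + "\n")


def read_dosages(path) -> GenotypeMatrix:
    meta_rows = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("##VAR\t"):
            _, snp, chrom, pos, a1, a2, freq = line.rstrip("\n").split("\t")
            meta_rows.append({"snp_id": snp, "chrom": chrom, "pos": int(pos),
                              "counted_allele": a1, "other_allele": a2,
                              "freq": float(freq)})
        else:
            body_start = i
            break
    header = lines[body_start].rstrip("\n").split("\t")
    variants = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS)
    if header[1:] != list(variants["snp_id"]):
        raise ValueError("dosage header does not match metadata block")
    samples, rows = [], []
    for line in lines[body_start + 1:]:
        parts = line.rstrip("\n").split("\t")
        samples.append(parts[0])
        rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
    return GenotypeMatrix(samples, variants, np.asarray(rows, dtype=float))


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Read a VCF (GT field) into a dosage matrix counting ALT alleles."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows, cols = [], []
    for var in vcf:
        gts = var.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), np.nan,
                        (gts > 0).sum(axis=1).astype(float))
        cols.append(dose)
        freq = (np.nanmean(dose) / 2.0) if np.isfinite(dose).any() else np.nan
        meta_rows.append({"snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                          "chrom": str(var.CHROM), "pos": int(var.POS),
                          "counted_allele": var.ALT[0], "other_allele": var.REF,
                          "freq": freq})
    variants = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(samples, variants,
                          np.column_stack(cols) if cols else
                          np.empty((len(samples), 0)))
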