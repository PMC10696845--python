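"""Two-sample MR: selection, harmonization, filters, estimators, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsphewas import mr, syndata
from prsphewas.syndata import SynthMRConfig

from conftest import make_sumstats, mri_from_pair


def _row(snp, p=0.5, beta=0.1, se=0.05, ea="A", oa="G", eaf=0.3, n=10000.0,
         chrom="1", pos=100):
    return (snp, chrom, pos, ea, oa, eaf, beta, se, p, n)


def _mri(rows):
    """MR input from (snp, bx, sx, by, sy [, nx, ny]) tuples."""
    recs = []
    for r in rows:
        snp, bx, sx, by, sy = r[:5]
        nx = r[5] if len(r) > 5 else 100000.0
        ny = r[6] if len(r) > 6 else 100000.0
        recs.append({"snp_id": snp, "eaf": 0.3,
                     "beta_exposure": bx, "se_exposure": sx,
                     "p_exposure": 1e-10, "n_exposure": nx,
                     "beta_outcome": by, "se_outcome": sy,
                     "p_outcome": 0.5, "n_outcome": ny})
    return pd.DataFrame(recs, columns=mr.MRINPUT_COLUMNS)


class TestSelectInstruments:
    def test_threshold_is_strict(self):
        ss = make_sumstats([_row("rs1", p=5e-8, pos=100),
                            _row("rs2", p=4.9e-8, pos=5_000_000)])
        inst = mr.select_instruments(ss)
        assert list(inst.table["snp_id"]) == ["rs2"]

    def test_distance_clumping_keeps_lower_p(self):
        ss = make_sumstats([_row("rs1", p=1e-10, pos=100),
                            _row("rs2", p=1e-9, pos=500_000)])
        inst = mr.select_instruments(ss)
        assert list(inst.table["snp_id"]) == ["rs1"]

    def test_unlinked_instruments_all_retained(self):
        e, _, _ = syndata.gen_two_sample_sumstats(
            SynthMRConfig(k_instruments=50, seed=31))
        inst = mr.select_instruments(e)
        assert inst.n_variants == 50

    def test_ld_matrix_clumping(self):
        ss = make_sumstats([_row("rs1", p=1e-10, pos=100),
                            _row("rs2", p=1e-9, pos=5_000_000),
                            _row("rs3", p=1e-8, pos=200_000_000)])
        ld = pd.DataFrame(np.eye(3), index=["rs1", "rs2", "rs3"],
                          columns=["rs1", "rs2", "rs3"])
        ld.loc["rs1", "rs2"] = ld.loc["rs2", "rs1"] = 0.5
        inst = mr.select_instruments(ss, ld=ld)
        assert list(inst.table["snp_id"]) == ["rs1", "rs3"]

    def test_no_instruments_rejected(self):
        ss = make_sumstats([_row("rs1", p=0.5)])
        with pytest.raises(ValueError, match="significance"):
            mr.select_instruments(ss)


class TestHarmonize:
    def test_swapped_alleles_flip_beta(self):
        e = make_sumstats([_row("rs1", beta=0.1, ea="A", oa="G")])
        o = make_sumstats([_row("rs1", beta=0.05, ea="G", oa="A", eaf=0.7)])
        mri, report = mr.harmonize(e, o)
        assert mri["beta_outcome"].iloc[0] == pytest.approx(-0.05)
        assert report["flipped"] == 1

    def test_palindromic_mid_frequency_dropped(self):
        e = make_sumstats([_row("rs1", ea="A", oa="T", eaf=0.50)])
        o = make_sumstats([_row("rs1", ea="A", oa="T", eaf=0.50)])
        mri, report = mr.harmonize(e, o)
        assert len(mri) == 0
        assert report["dropped_palindromic"] == 1

    def test_palindromic_informative_frequency_aligned(self):
        e = make_sumstats([_row("rs1", ea="A", oa="T", eaf=0.2, beta=0.1)])
        o = make_sumstats([_row("rs1", ea="A", oa="T", eaf=0.8, beta=0.05)])
        mri, report = mr.harmonize(e, o)
        assert mri["beta_outcome"].iloc[0] == pytest.approx(-0.05)

    def test_aligned_input_identity(self):
        e, o, _ = syndata.gen_two_sample_sumstats(SynthMRConfig(seed=32))
        mri, report = mr.harmonize(e, o)
        assert len(mri) == 30
        assert report["flipped"] == report["dropped_palindromic"] == 0
        np.testing.assert_allclose(mri["beta_outcome"], o.table["beta"])

    def test_strand_flip_resolved_via_complement(self):
        e = make_sumstats([_row("rs1", ea="A", oa="G", beta=0.1)])
        o = make_sumstats([_row("rs1", ea="T", oa="C", beta=0.05)])
        mri, report = mr.harmonize(e, o)
        assert mri["beta_outcome"].iloc[0] == pytest.approx(0.05)
        assert report["strand_flipped"] == 1

    def test_incompatible_alleles_dropped(self):
        e = make_sumstats([_row("rs1", ea="A", oa="G")])
        o = make_sumstats([_row("rs1", ea="A", oa="C")])
        mri, report = mr.harmonize(e, o)
        assert len(mri) == 0
        assert report["dropped_incompatible"] == 1


class TestFandSteiger:
    def test_f_closed_form(self):
        mri = _mri([("rs1", 0.1, 0.01, 0.0, 0.01),
                    ("rs2", 0.01, 0.01, 0.0, 0.01)])
        out, F = mr.f_statistics(mri)
        assert F.tolist() == pytest.approx([100.0, 1.0])
        assert list(out["snp_id"]) == ["rs1"]

    def test_f_sign_invariant(self):
        a = _mri([("rs1", 0.1, 0.01, 0.0, 0.01)])
        b = _mri([("rs1", -0.1, 0.01, 0.0, 0.01)])
        assert mr.f_statistics(a)[1].iloc[0] == mr.f_statistics(b)[1].iloc[0]

    def test_equal_z_larger_exposure_n_removed(self):
        # r2 = z^2/(z^2+n-2) decreases with n at fixed z
        mri = _mri([("rs1", 0.1, 0.01, 0.1, 0.01, 200000.0, 100000.0)])
        out, r2 = mr.steiger_filter(mri)
        assert len(out) == 0
        assert r2["r2_exposure"].iloc[0] < r2["r2_outcome"].iloc[0]

    def test_equal_r2_removed_strict(self):
        mri = _mri([("rs1", 0.1, 0.01, 0.1, 0.01, 50000.0, 50000.0)])
        out, _ = mr.steiger_filter(mri)
        assert len(out) == 0

    def test_strong_exposure_all_retained(self):
        e, o, _ = syndata.gen_two_sample_sumstats(
            SynthMRConfig(k_instruments=30, true_b=-0.2, seed=33))
        out, _ = mr.steiger_filter(mri_from_pair(e, o))
        assert len(out) == 30

    def test_small_n_rejected(self):
        mri = _mri([("rs1", 0.1, 0.01, 0.1, 0.01, 2.0, 100.0)])
        with pytest.raises(ValueError):
            mr.steiger_filter(mri)


class TestWaldAndIVW:
    def test_wald_closed_form(self):
        rec = _mri([("rs1", 0.1, 0.01, -0.02, 0.005)]).iloc[0]
        r = mr.wald_ratio(rec)
        assert r.b == pytest.approx(-0.2)
        assert r.se == pytest.approx(0.05)

    def test_wald_zero_outcome(self):
        rec = _mri([("rs1", 0.1, 0.01, 0.0, 0.005)]).iloc[0]
        assert mr.wald_ratio(rec).b == 0.0

    def test_wald_zero_exposure_rejected(self):
        rec = _mri([("rs1", 0.0, 0.01, 0.05, 0.005)]).iloc[0]
        with pytest.raises(ValueError):
            mr.wald_ratio(rec)

    def test_ivw_k1_equals_wald(self):
        mri = _mri([("rs1", 0.1, 0.01, -0.02, 0.005)])
        r_ivw = mr.ivw(mri)
        r_wald = mr.wald_ratio(mri.iloc[0])
        assert r_ivw.b == r_wald.b
        assert r_ivw.se == r_wald.se

    def test_identical_ratios_no_heterogeneity(self):
        mri = _mri([("rs1", 0.1, 0.01, -0.02, 0.005),
                    ("rs2", 0.2, 0.01, -0.04, 0.005),
                    ("rs3", 0.05, 0.01, -0.01, 0.005)])
        r = mr.ivw(mri)
        assert r.Q == pytest.approx(0.0, abs=1e-20)
        assert r.Q_p == pytest.approx(1.0)
        assert r.b == pytest.approx(-0.2)

    def test_quick_parameter_recovery(self):
        bs = []
        for i in range(50):
            e, o, _ = syndata.gen_two_sample_sumstats(
                SynthMRConfig(k_instruments=30, true_b=-0.2, seed=600 + i))
            bs.append(mr.ivw(mri_from_pair(e, o)).b)
        assert np.mean(bs) == pytest.approx(-0.2, abs=0.02)

    def test_sign_coherence(self):
        e, o, _ = syndata.gen_two_sample_sumstats(SynthMRConfig(seed=34))
        mri = mri_from_pair(e, o)
        flipped = mri.copy()
        flipped["beta_exposure"] = -flipped["beta_exposure"]
        assert mr.ivw(flipped).b == pytest.approx(-mr.ivw(mri).b)
        assert mr.mr_egger(flipped).b == pytest.approx(-mr.mr_egger(mri).b)
        wm1 = mr.weighted_median(mri, seed=1)
        wm2 = mr.weighted_median(flipped, seed=1)
        assert wm2.b == pytest.approx(-wm1.b)


class TestEgger:
    def test_collinear_points_exact_fit(self):
        mri = _mri([("rs1", 0.1, 0.01, -0.02, 0.005),
                    ("rs2", 0.2, 0.01, -0.04, 0.005),
                    ("rs3", 0.3, 0.01, -0.06, 0.005)])
        r = mr.mr_egger(mri)
        assert r.b == pytest.approx(-0.2, abs=1e-10)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            mr.mr_egger(_mri([("rs1", 0.1, 0.01, 0.0, 0.01),
                              ("rs2", 0.2, 0.01, 0.0, 0.01)]))

    def test_intercept_type_one_error(self):
        hits = 0
        reps = 100
        for i in range(reps):
            e, o, _ = syndata.gen_two_sample_sumstats(
                SynthMRConfig(k_instruments=50, true_b=-0.2, seed=700 + i))
            hits += mr.mr_egger(mri_from_pair(e, o)).intercept_p < 0.05
        assert hits / reps < 0.12


class TestWeightedMedian:
    def test_equal_weights_odd_k_middle_ratio(self):
        # sx = 0 so the three ratio variances (hence weights) are identical
        mri = _mri([("rs1", 0.1, 0.0, 0.01, 0.005),
                    ("rs2", 0.1, 0.0, 0.02, 0.005),
                    ("rs3", 0.1, 0.0, 0.03, 0.005)])
        r = mr.weighted_median(mri, n_boot=10, seed=1)
        assert r.b == pytest.approx(0.2)

    def test_bootstrap_seed_reproducible(self):
        e, o, _ = syndata.gen_two_sample_sumstats(SynthMRConfig(seed=35))
        mri = mri_from_pair(e, o)
        r1 = mr.weighted_median(mri, seed=42)
        r2 = mr.weighted_median(mri, seed=42)
        assert r1.se == r2.se

    def test_robust_to_forty_percent_pleiotropy(self):
        bs = []
        for i in range(40):
            cfg = SynthMRConfig(k_instruments=30, true_b=-0.2,
                                n_outliers=12, outlier_shift=0.05,
                                n_exposure=2_000_000, n_outcome=2_000_000,
                                seed=800 + i)
            e, o, _ = syndata.gen_two_sample_sumstats(cfg)
            bs.append(mr.weighted_median(mri_from_pair(e, o), n_boot=50,
                                         seed=i).b)
        assert np.mean(bs) == pytest.approx(-0.2, abs=0.03)


class TestLeaveOneOut:
    def test_k_rows_and_homogeneous_stability(self):
        e, o, _ = syndata.gen_two_sample_sumstats(
            SynthMRConfig(k_instruments=20, seed=36))
        mri = mri_from_pair(e, o)
        loo = mr.leave_one_out(mri)
        full = mr.ivw(mri)
        assert len(loo) == 20
        assert np.all(np.abs(loo["b"] - full.b) < 0.05)

    def test_gross_outlier_shifts_most(self):
        rows = [(f"rs{j}", 0.1, 0.005, -0.02, 0.005) for j in range(9)]
        rows.append(("rs_out", 0.1, 0.005, 0.08, 0.005))
        loo = mr.leave_one_out(_mri(rows))
        shifts = np.abs(loo["b"] - mr.ivw(_mri(rows)).b)
        assert loo.loc[shifts.idxmax(), "omitted"] == "rs_out"

    def test_k2_reduces_to_wald_ratios(self):
        mri = _mri([("rs1", 0.1, 0.01, -0.02, 0.005),
                    ("rs2", 0.2, 0.01, -0.02, 0.005)])
        loo = mr.leave_one_out(mri)
        assert loo["b"].tolist() == pytest.approx([-0.1, -0.2])


class TestMRPresso:
    def test_seed_reproducible(self):
        cfg = SynthMRConfig(k_instruments=20, n_outliers=2, seed=37)
        e, o, _ = syndata.gen_two_sample_sumstats(cfg)
        mri = mri_from_pair(e, o)
        _, a1, rep1 = mr.mr_presso(mri, seed=5)
        _, a2, rep2 = mr.mr_presso(mri, seed=5)
        assert rep1["outliers"] == rep2["outliers"]
        assert a1.b == a2.b

    def test_gross_outliers_flagged_and_adjusted(self):
        cfg = SynthMRConfig(k_instruments=30, true_b=-0.2, n_outliers=2,
                            outlier_shift=0.1, seed=38)
        e, o, truth = syndata.gen_two_sample_sumstats(cfg)
        raw, adj, report = mr.mr_presso(mri_from_pair(e, o), seed=5)
        assert set(truth["outlier_snps"]) <= set(report["outliers"])
        assert abs(adj.b - (-0.2)) < abs(raw.b - (-0.2))
        assert report["global_p"] < 0.01

    def test_no_outliers_adjusted_equals_ivw(self):
        e, o, _ = syndata.gen_two_sample_sumstats(
            SynthMRConfig(k_instruments=20, seed=39))
        mri = mri_from_pair(e, o)
        raw, adj, report = mr.mr_presso(mri, seed=5)
        assert report["outliers"] == []
        assert adj.b == mr.ivw(mri).b

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            mr.mr_presso(_mri([("rs1", 0.1, 0.01, 0.0, 0.01)] * 3), seed=1)


class TestMVMR:
    def test_single_exposure_equals_ivw(self):
        e, o, _ = syndata.gen_two_sample_sumstats(SynthMRConfig(seed=40))
        mri = mri_from_pair(e, o).rename(
            columns={"beta_exposure": "beta_x", "se_exposure": "se_x"})
        res = mr.mvmr(mri, ["x"])
        ivw_b = mr.ivw(mri.rename(columns={"beta_x": "beta_exposure",
                                           "se_x": "se_exposure"})).b
        assert res[0].b == pytest.approx(ivw_b)

    def test_duplicated_exposure_rank_error(self):
        e, o, _ = syndata.gen_two_sample_sumstats(SynthMRConfig(seed=41))
        mri = mri_from_pair(e, o)
        mri["beta_x1"] = mri["beta_exposure"]
        mri["beta_x2"] = mri["beta_exposure"]
        with pytest.raises(ValueError, match="collinear"):
            mr.mvmr(mri, ["x1", "x2"])

    def test_conditional_effects_with_correlated_exposures(self, rng):
        # exposure 1 causal (b=-0.2), exposure 2 null but correlated with 1
        bs1, bs2 = [], []
        for i in range(40):
            r = np.random.default_rng(900 + i)
            k = 40
            g1 = r.uniform(0.03, 0.1, k)
            g2 = 0.6 * g1 + 0.4 * r.uniform(0.03, 0.1, k)
            sy = np.full(k, 0.004)
            by = -0.2 * g1 + 0.0 * g2 + r.normal(0, sy)
            mri = pd.DataFrame({"beta_x1": g1, "beta_x2": g2,
                                "beta_outcome": by, "se_outcome": sy})
            res = mr.mvmr(mri, ["x1", "x2"])
            bs1.append(res[0].b)
            bs2.append(res[1].b)
        assert np.mean(bs1) == pytest.approx(-0.2, abs=0.02)
        assert np.mean(bs2) == pytest.approx(0.0, abs=0.02)


class TestFDR:
    def _bh_naive(self, p):
        n = len(p)
        order = np.argsort(p)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        adj = np.empty(n)
        for i in range(n):
            candidates = [n * p[j] / ranks[j] for j in range(n)
                          if p[j] >= p[i]]
            adj[i] = min(1.0, min(candidates))
        return adj

    def test_bh_closed_form(self):
        df = pd.DataFrame({"direction": ["f"] * 3, "method": ["ivw"] * 3,
                           "p": [0.01, 0.02, 0.03]})
        out = mr.fdr_within_groups(df)
        assert out["p_adj"].tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton_group(self):
        df = pd.DataFrame({"direction": ["f"], "method": ["ivw"],
                           "p": [0.04]})
        out = mr.fdr_within_groups(df)
        assert out["p_adj"].iloc[0] == pytest.approx(0.04)

    def test_groups_independent(self):
        df = pd.DataFrame({"direction": ["f", "f", "r"],
                           "method": ["ivw", "egger", "ivw"],
                           "p": [0.01, 0.02, 0.03]})
        out = mr.fdr_within_groups(df)
        assert out["p_adj"].tolist() == pytest.approx([0.01, 0.02, 0.03])

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            p = rng.uniform(size=n)
            df = pd.DataFrame({"direction": ["f"] * n, "method": ["ivw"] * n,
                               "p": p})
            out = mr.fdr_within_groups(df)
            np.testing.assert_allclose(out["p_adj"], self._bh_naive(p),
                                       atol=1e-12)


class TestCrossMethodCoherence:
    def test_noiseless_pleiotropy_free_agreement(self):
        cfg = SynthMRConfig(k_instruments=20, true_b=-0.2,
                            n_exposure=10 ** 10, n_outcome=10 ** 10, seed=43)
        e, o, _ = syndata.gen_two_sample_sumstats(cfg)
        mri = mri_from_pair(e, o)
        b_ivw = mr.ivw(mri).b
        b_egger = mr.mr_egger(mri).b
        b_wm = mr.weighted_median(mri, n_boot=50, seed=1).b
        assert abs(b_ivw - b_egger) < 0.01
        assert abs(b_ivw - b_wm) < 0.01

    def test_filters_never_increase_k(self):
        e, o, _ = syndata.gen_two_sample_sumstats(
            SynthMRConfig(k_instruments=30, seed=44))
        mri0 = mri_from_pair(e, o)
        mri1, _ = mr.f_statistics(mri0)
        mri2, _ = mr.steiger_filter(mri1)
        assert len(mri2) <= len(mri1) <= len(mri0)
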