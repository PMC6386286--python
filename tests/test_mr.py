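"""MR estimators against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinmr import (
    clump,
    cochran_q,
    egger,
    harmonize,
    ivw,
    leave_one_out,
    single_snp_table,
    wald_ratio,
    weighted_mode,
)
from twinmr.mr import HarmonizedMRData

from conftest import make_harmonized


def _gwas(snps, ea, oa, eaf, beta, se=0.01):
    n = len(snps)
    beta = np.asarray(beta, dtype=float)
    se_arr = np.full(n, se)
    return pd.DataFrame({
        "SNP": snps, "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se_arr,
        "pval": 2.0 * stats.norm.sf(np.abs(beta) / se_arr),
        "samplesize": 10000,
    })


class TestHarmonize:
    def test_identical_coding_is_identity(self):
        ex = _gwas(["rs1", "rs2"], ["A", "C"], ["G", "T"], [0.3, 0.4],
                   [0.1, -0.2])
        out = _gwas(["rs1", "rs2"], ["A", "C"], ["G", "T"], [0.31, 0.41],
                    [0.05, 0.07])
        harm = harmonize(ex, out)
        assert harm.log == []
        np.testing.assert_allclose(harm.data["beta_outcome"], [0.05, 0.07])

    def test_swapped_alleles_flip_outcome_sign(self):
        ex = _gwas(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _gwas(["rs1"], ["G"], ["A"], [0.7], [0.05])
        harm = harmonize(ex, out)
        assert harm.data["beta_outcome"].iloc[0] == pytest.approx(-0.05)
        assert harm.data["eaf_outcome"].iloc[0] == pytest.approx(0.3)
        assert harm.log[0]["action"] == "flip"

    def test_strand_flip_resolved(self):
        ex = _gwas(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _gwas(["rs1"], ["T"], ["C"], [0.3], [0.05])
        harm = harmonize(ex, out)
        assert harm.data["beta_outcome"].iloc[0] == pytest.approx(0.05)

    def test_irreconcilable_alleles_dropped_with_reason(self):
        ex = _gwas(["rs1"], ["A"], ["G"], [0.3], [0.1])
        out = _gwas(["rs1"], ["A"], ["C"], [0.3], [0.05])
        harm = harmonize(ex, out)
        assert harm.n_snps == 0
        assert harm.log[0]["reason"] == "irreconcilable alleles"

    @pytest.mark.parametrize("eaf_x,eaf_y,expect", [
        (0.5, 0.5, "dropped"),      # ambiguous frequency
        (0.45, 0.45, "dropped"),    # inside the ambiguity window
        (0.2, 0.25, "kept"),        # same side: aligned as-is
        (0.2, 0.8, "flipped"),      # opposite sides: strand inferred
    ])
    def test_palindromic_policy_enumeration(self, eaf_x, eaf_y, expect):
        ex = _gwas(["rs1"], ["A"], ["T"], [eaf_x], [0.1])
        out = _gwas(["rs1"], ["A"], ["T"], [eaf_y], [0.05])
        harm = harmonize(ex, out)
        if expect == "dropped":
            assert harm.n_snps == 0
        elif expect == "kept":
            assert harm.data["beta_outcome"].iloc[0] == pytest.approx(0.05)
        else:
            assert harm.data["beta_outcome"].iloc[0] == pytest.approx(-0.05)

    def test_drop_policy_removes_all_palindromic(self):
        ex = _gwas(["rs1", "rs2"], ["A", "A"], ["T", "G"], [0.2, 0.3],
                   [0.1, 0.1])
        out = _gwas(["rs1", "rs2"], ["A", "A"], ["T", "G"], [0.2, 0.3],
                    [0.05, 0.05])
        harm = harmonize(ex, out, palindromic_policy="drop")
        assert harm.data["SNP"].tolist() == ["rs2"]

    def test_harmonize_is_idempotent_on_its_output(self):
        ex = _gwas(["rs1", "rs2", "rs3"], ["A", "C", "A"], ["G", "T", "T"],
                   [0.3, 0.6, 0.2], [0.1, -0.2, 0.15])
        out = _gwas(["rs1", "rs2", "rs3"], ["G", "C", "A"], ["A", "T", "T"],
                    [0.7, 0.6, 0.8], [0.05, 0.07, -0.03])
        harm = harmonize(ex, out)
        ex2, out2 = harm.to_tables()
        harm2 = harmonize(ex2, out2)
        assert harm2.log == []
        pd.testing.assert_frame_equal(
            harm.data.reset_index(drop=True)[harm2.data.columns],
            harm2.data.reset_index(drop=True), check_dtype=False,
            atol=1e-12)


class TestClump:
    def _ld(self, snps, entries=None):
        mat = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
        for (a, b), r2 in (entries or {}).items():
            mat.loc[a, b] = mat.loc[b, a] = r2
        return mat

    def test_identity_ld_retains_all(self):
        table = _gwas(["x1", "x2", "x3"], "A", "G", 0.3, [0.1, 0.2, 0.3])
        out = clump(table, self._ld(["x1", "x2", "x3"]), 0.001)
        assert out["SNP"].tolist() == ["x1", "x2", "x3"]

    def test_perfect_ld_keeps_smaller_p(self):
        table = _gwas(["x1", "x2"], "A", "G", 0.3, [0.3, 0.1])  # x1 smaller p
        out = clump(table, self._ld(["x1", "x2"], {("x1", "x2"): 1.0}), 0.1)
        assert out["SNP"].tolist() == ["x1"]

    def test_chain_pruning_hand_oracle(self):
        # p-values increase x1 < x2 < x3; x1-x2 and x2-x3 in LD, x1-x3 not
        table = _gwas(["x1", "x2", "x3"], "A", "G", 0.3, [0.5, 0.4, 0.3])
        ld = self._ld(["x1", "x2", "x3"],
                      {("x1", "x2"): 0.9, ("x2", "x3"): 0.9, ("x1", "x3"): 0.1})
        out = clump(table, ld, 0.5)
        assert out["SNP"].tolist() == ["x1", "x3"]

    def test_missing_ld_entries_named(self):
        table = _gwas(["x1", "x2"], "A", "G", 0.3, [0.1, 0.2])
        with pytest.raises(ValueError, match="x2"):
            clump(table, self._ld(["x1"]), 0.1)


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,se_y,b,se", [
        (0.5, 0.0, 0.05, 0.0, 0.1),
        (0.4, 0.4, 0.02, 1.0, 0.05),
        (0.5, 0.1, 0.05, 0.2, 0.1),     # delta-method oracle
        (-0.5, 0.1, 0.05, -0.2, 0.1),   # sign handled via |b_exp|
    ])
    def test_ratio_and_delta_se(self, bx, by, se_y, b, se):
        est = wald_ratio(bx, by, se_y)
        assert est.b == pytest.approx(b)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.05)


class TestIvw:
    def test_duplicated_snp_equals_wald_ratio(self):
        harm = make_harmonized([0.4, 0.4], [0.12, 0.12], se_y=0.05)
        est = ivw(harm)
        assert est.b == pytest.approx(wald_ratio(0.4, 0.12, 0.05).b)

    def test_matches_weighted_least_squares_oracle(self):
        bx = np.array([0.2, 0.5, -0.3])
        by = np.array([0.06, 0.14, -0.10])
        se_y = np.array([0.01, 0.02, 0.015])
        harm = make_harmonized(bx, by, se_y=se_y)
        w = se_y**-2
        oracle = np.sum(w * bx * by) / np.sum(w * bx**2)
        oracle_se = np.sqrt(1.0 / np.sum(w * bx**2))
        est = ivw(harm, "fixed")
        assert est.b == pytest.approx(oracle, rel=1e-10)
        assert est.se == pytest.approx(oracle_se, rel=1e-10)

    def test_multiplicative_random_inflates_only_when_overdispersed(self):
        bx = np.array([0.2, 0.5, -0.3, 0.4])
        by_exact = 0.3 * bx
        harm = make_harmonized(bx, by_exact, se_y=0.05)
        assert ivw(harm, "multiplicative_random").se == pytest.approx(
            ivw(harm, "fixed").se)  # underdispersed: floor at 1
        by_noisy = by_exact + np.array([0.3, -0.25, 0.28, -0.31])
        harm2 = make_harmonized(bx, by_noisy, se_y=0.05)
        assert (ivw(harm2, "multiplicative_random").se
                > ivw(harm2, "fixed").se)

    def test_outcome_scaling_equivariance(self):
        bx = np.array([0.2, 0.5, -0.3])
        by = np.array([0.06, 0.14, -0.10])
        harm = make_harmonized(bx, by, se_y=0.01)
        harm_k = make_harmonized(bx, 3.0 * by, se_y=0.03)
        est, est_k = ivw(harm), ivw(harm_k)
        assert est_k.b == pytest.approx(3.0 * est.b, rel=1e-10)
        assert est_k.b / est_k.se == pytest.approx(est.b / est.se, rel=1e-10)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError, match="wald"):
            ivw(make_harmonized([0.4], [0.1]))


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.05 + 0.3 * bx
        slope, intercept = egger(make_harmonized(bx, by, se_y=0.02))
        assert slope.b == pytest.approx(0.3, abs=1e-10)
        assert intercept.b == pytest.approx(0.05, abs=1e-10)

    def test_matches_wls_oracle(self):
        bx = np.array([0.2, 0.5, 0.3, 0.7])
        by = np.array([0.09, 0.16, 0.12, 0.23])
        se_y = np.array([0.01, 0.02, 0.015, 0.01])
        slope, intercept = egger(make_harmonized(bx, by, se_y=se_y))
        w = se_y**-2
        x = np.column_stack([np.ones(4), bx])
        coef = np.linalg.solve(x.T @ (w[:, None] * x), x.T @ (w * by))
        assert intercept.b == pytest.approx(coef[0], rel=1e-10)
        assert slope.b == pytest.approx(coef[1], rel=1e-10)
        resid = by - x @ coef
        sigma2 = max(1.0, np.sum(w * resid**2) / 2)
        cov = np.linalg.inv(x.T @ (w[:, None] * x)) * sigma2
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)
        assert slope.p == pytest.approx(
            2 * stats.t.sf(abs(coef[1] / np.sqrt(cov[1, 1])), 2), rel=1e-10)

    def test_orientation_makes_exposure_betas_nonnegative(self):
        bx = np.array([0.2, -0.4, 0.6])
        by = 0.3 * bx
        slope, intercept = egger(make_harmonized(bx, by, se_y=0.02))
        assert slope.b == pytest.approx(0.3, abs=1e-9)
        assert intercept.b == pytest.approx(0.0, abs=1e-9)

    def test_outcome_translation_shifts_intercept_only(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.3 * bx + np.array([0.01, -0.02, 0.005, 0.0])
        s0, i0 = egger(make_harmonized(bx, by, se_y=0.02))
        s1, i1 = egger(make_harmonized(bx, by + 0.07, se_y=0.02))
        assert s1.b == pytest.approx(s0.b, rel=1e-10)
        assert i1.b == pytest.approx(i0.b + 0.07, rel=1e-10)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            egger(make_harmonized([0.2, 0.4], [0.06, 0.12]))


class TestWeightedMode:
    def test_point_mass_returns_common_ratio(self):
        harm = make_harmonized([0.2, 0.4, 0.5], [0.06, 0.12, 0.15], se_y=0.01)
        est = weighted_mode(harm, n_boot=50, seed=0)
        assert est.b == pytest.approx(0.3, abs=1e-9)
        assert est.se > 0.0

    def test_majority_invalid_instruments_mode_near_valid_ratio(self):
        """10 precise valid SNPs at ratio 0.3 beat 4 pleiotropic at 1.0."""
        rng = np.random.default_rng(12)
        bx = np.concatenate([rng.uniform(0.3, 0.6, 10), rng.uniform(0.3, 0.6, 4)])
        ratios = np.concatenate([rng.normal(0.3, 0.01, 10),
                                 rng.normal(1.0, 0.05, 4)])
        by = ratios * bx
        se_y = np.concatenate([np.full(10, 0.01), np.full(4, 0.02)])
        harm = make_harmonized(bx, by, se_y=se_y)
        est = weighted_mode(harm, n_boot=100, seed=1)
        assert abs(est.b - 0.3) < 0.05
        # the IVW compromise is pulled toward the pleiotropic cluster
        assert abs(ivw(harm).b - 0.3) > 2.0 * abs(est.b - 0.3)

    def test_matches_grid_search_density_oracle(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.2, 0.8, 12)
        by = 0.25 * bx + rng.normal(0, 0.02, 12)
        se_y = np.full(12, 0.02)
        harm = make_harmonized(bx, by, se_y=se_y)
        est = weighted_mode(harm, n_boot=10, seed=0)
        # independent brute-force maximization of the weighted kernel density
        ratio = by / bx
        se_r = se_y / np.abs(bx)
        w = se_r**-2
        w = w / w.sum()
        sd = ratio.std(ddof=1)
        mad = stats.median_abs_deviation(ratio, scale="normal")
        h = max(1e-8, 0.9 * min(sd, mad) / 12**0.2)
        grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 200_001)
        dens = np.zeros_like(grid)
        for r, wi in zip(ratio, w):
            dens += wi * np.exp(-0.5 * ((grid - r) / h) ** 2)
        oracle = grid[np.argmax(dens)]
        assert est.b == pytest.approx(oracle, abs=2 * (grid[1] - grid[0]) + 1e-3)

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.2, 0.8, 8)
        by = 0.4 * bx + rng.normal(0, 0.03, 8)
        harm = make_harmonized(bx, by, se_y=0.03)
        perm = rng.permutation(8)
        harm_p = make_harmonized(bx[perm], by[perm], se_y=0.03)
        a = weighted_mode(harm, n_boot=1, seed=0)
        b = weighted_mode(harm_p, n_boot=1, seed=0)
        assert a.b == pytest.approx(b.b, abs=1e-9)

    def test_invalid_phi_rejected(self):
        harm = make_harmonized([0.2, 0.4, 0.5], [0.06, 0.12, 0.15])
        with pytest.raises(ValueError):
            weighted_mode(harm, phi=0.0)


class TestCochranQ:
    def test_homogeneous_ratios_give_zero(self):
        harm = make_harmonized([0.2, 0.4, 0.5], [0.06, 0.12, 0.15], se_y=0.01)
        q, df, p = cochran_q(harm)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_matches_hand_summed_oracle(self):
        bx = np.array([0.2, 0.5, -0.3])
        by = np.array([0.07, 0.13, -0.11])
        se_y = np.array([0.01, 0.02, 0.015])
        q, df, p = cochran_q(make_harmonized(bx, by, se_y=se_y))
        ratio = by / bx
        w = (np.abs(bx) / se_y) ** 2
        b_ivw = np.sum(w * ratio) / np.sum(w)
        oracle = np.sum(w * (ratio - b_ivw) ** 2)
        assert q == pytest.approx(oracle, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(oracle, 2), rel=1e-10)

    def test_order_invariant(self):
        bx = np.array([0.2, 0.5, -0.3, 0.4])
        by = np.array([0.07, 0.13, -0.11, 0.1])
        a = cochran_q(make_harmonized(bx, by))
        b = cochran_q(make_harmonized(bx[::-1], by[::-1]))
        assert a[0] == pytest.approx(b[0], rel=1e-12)


class TestLeaveOneOut:
    def test_row_count_and_total_row(self):
        harm = make_harmonized([0.2, 0.4, 0.5, 0.3], [0.06, 0.13, 0.14, 0.1])
        table = leave_one_out(harm)
        assert len(table) == 5
        assert table["SNP"].iloc[-1] == "All"

    def test_outlier_omission_moves_estimate_most(self):
        bx = np.array([0.3, 0.4, 0.5, 0.6, 0.45])
        by = 0.3 * bx
        by[2] += 0.5  # planted outlier
        harm = make_harmonized(bx, by, se_y=0.02)
        table = leave_one_out(harm)
        full_b = table.loc[table["SNP"] == "All", "b"].iloc[0]
        moves = (table[table["SNP"] != "All"]
                 .assign(move=lambda d: (d["b"] - full_b).abs()))
        outlier_snp = harm.data["SNP"].iloc[2]
        assert moves.loc[moves["move"].idxmax(), "SNP"] == outlier_snp
        # oracle: recompute each left-out IVW from scratch
        for rec in table[table["SNP"] != "All"].itertuples(index=False):
            keep = harm.data["SNP"] != rec.SNP
            sub = make_harmonized(bx[keep.to_numpy()], by[keep.to_numpy()],
                                  se_y=0.02)
            assert rec.b == pytest.approx(ivw(sub).b, rel=1e-10)

    def test_homogeneous_case_all_within_ci(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.3, 0.7, 10)
        by = 0.2 * bx + rng.normal(0, 0.01, 10)
        table = leave_one_out(make_harmonized(bx, by, se_y=0.01))
        full_b = table.loc[table["SNP"] == "All", "b"].iloc[0]
        rest = table[table["SNP"] != "All"]
        assert ((rest["b"] - 1.96 * rest["se"] <= full_b)
                & (full_b <= rest["b"] + 1.96 * rest["se"])).all()


class TestSingleSnpTable:
    def test_ci_bounds_and_funnel_columns(self):
        bx = np.array([0.2, 0.4, 0.5])
        by = np.array([0.07, 0.13, 0.14])
        se_y = np.array([0.01, 0.02, 0.015])
        table = single_snp_table(make_harmonized(bx, by, se_y=se_y))
        np.testing.assert_allclose(table["ci_low"],
                                   table["b"] - 1.96 * table["se"], atol=1e-4)
        np.testing.assert_allclose(table["inv_se"], 1.0 / table["se"],
                                   rtol=1e-12)
        # funnel x/y recomputed independently per SNP
        for rec in table[table["method"] == "wald"].itertuples(index=False):
            i = [f"rs{j + 1:04d}" for j in range(3)].index(rec.SNP)
            assert rec.b == pytest.approx(by[i] / bx[i], rel=1e-12)
            assert rec.inv_se == pytest.approx(abs(bx[i]) / se_y[i], rel=1e-12)

    def test_summary_rows_present(self):
        harm = make_harmonized([0.2, 0.4, 0.5], [0.07, 0.13, 0.14])
        table = single_snp_table(harm)
        assert set(table.loc[table["SNP"] == "All", "method"]) == {
            "ivw_fe", "egger_slope"}

    def test_empty_input_fails_informatively(self):
        empty = HarmonizedMRData(pd.DataFrame(columns=["SNP"]))
        with pytest.raises(ValueError, match="harmonization"):
            single_snp_table(empty)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_ivw_between_min_and_max_ratio_property(seed):
    """The IVW estimate is a convex combination of the per-SNP ratios."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    bx = rng.uniform(0.1, 1.0, n) * rng.choice([-1, 1], n)
    by = rng.normal(0, 0.2, n)
    harm = make_harmonized(bx, by, se_y=rng.uniform(0.01, 0.1, n))
    est = ivw(harm)
    ratios = by / bx
    assert ratios.min() - 1e-12 <= est.b <= ratios.max() + 1e-12
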