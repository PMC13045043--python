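"""LD matrix construction and the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrcoloc import (LDMatrix, make_ar1_ld, scenario_preset,
                     simulate_instruments, simulate_region)
from mrcoloc.annotate import ld_between
from mrcoloc.simulate import (MIN_EXPECTED_Z, InstrumentScenario,
                              RegionScenario, scenario_from_yaml)


class TestAr1Ld:
    def test_rho_zero_gives_identity(self):
        ld = make_ar1_ld(5, 0.0)
        np.testing.assert_array_equal(ld.r, np.eye(5))

    def test_lag_two_correlation(self):
        ld = make_ar1_ld(10, 0.9)
        assert ld.r[3, 5] == pytest.approx(0.81)
        assert ld.r2_between("snp_4", "snp_6") == pytest.approx(0.81 ** 2)

    def test_positive_definite_at_high_rho(self):
        ld = make_ar1_ld(200, 0.95)
        assert np.linalg.eigvalsh(ld.r).min() > 0

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            make_ar1_ld(5, 1.0)
        with pytest.raises(ValueError):
            make_ar1_ld(5, -0.1)

    def test_submatrix_alignment_and_io(self, tmp_path):
        ld = make_ar1_ld(6, 0.5)
        sub = ld.submatrix(["snp_5", "snp_2"])
        assert sub.r[0, 1] == pytest.approx(0.5 ** 3)
        f = tmp_path / "ld.tsv"
        ld.to_file(f)
        back = LDMatrix.from_file(f)
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r, ld.r, atol=1e-9)

    def test_ld_between_lookup(self):
        ld = make_ar1_ld(10, 0.9)
        assert ld_between(ld, "snp_1", "snp_1") == pytest.approx(1.0)
        assert ld_between(ld, "snp_1", "snp_3") == pytest.approx(0.6561)
        with pytest.raises(KeyError):
            ld_between(ld, "snp_1", "nope")

    def test_block_structure_zero_between_blocks(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.8
        r[2, 3] = r[3, 2] = 0.7
        ld = LDMatrix(["a", "b", "c", "d"], r)
        assert ld_between(ld, "a", "c") == 0.0


class TestInstrumentSimulation:
    def test_fixed_seed_is_bit_identical(self):
        scn = scenario_preset("table3_bft", seed=7)
        a = simulate_instruments(scn)
        b = simulate_instruments(scenario_preset("table3_bft", seed=7))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_true_effects_guarantee_significance(self):
        # the truncation contract: every true effect has expected |z| >= 6,
        # i.e. the underlying signal is genome-wide significant (p < 2e-9)
        scn = InstrumentScenario(m=300, b_xy_true=0.2, n_exp=20_000, n_out=20_000,
                                 seed=3, noise_free=True)
        pair = simulate_instruments(scn)
        z = np.abs(pair.df["bzx"] / pair.df["se_zx"])
        assert (z >= MIN_EXPECTED_Z).all()
        assert (pair.df["p_zx"] < 2e-9).all()

    def test_null_scenario_mean_ratio_near_zero(self):
        scn = InstrumentScenario(m=1000, b_xy_true=0.0, n_exp=50_000,
                                 n_out=50_000, seed=11)
        pair = simulate_instruments(scn)
        ratio = pair.df["bzy"] / pair.df["bzx"]
        mc_se = ratio.std(ddof=1) / np.sqrt(len(ratio))
        assert abs(ratio.mean()) < 3 * mc_se

    def test_empirical_se_matches_nominal(self):
        # at fixed maf the outcome-residual spread must match the nominal SEs
        reps = 10_000
        scn = InstrumentScenario(m=reps, b_xy_true=0.1, n_exp=30_000,
                                 n_out=30_000, maf_range=(0.3, 0.3), seed=5)
        pair = simulate_instruments(scn)
        resid = pair.df["bzy"] - 0.1 * pair.df["bzx"]
        # var(resid) = se_zy^2 + 0.1^2 se_zx^2 (independent errors)
        expected = np.sqrt(pair.df["se_zy"].iloc[0] ** 2
                           + 0.01 * pair.df["se_zx"].iloc[0] ** 2)
        assert resid.std(ddof=1) == pytest.approx(expected, rel=0.05)

    def test_pleiotropy_shifts_only_listed_instruments(self):
        scn = InstrumentScenario(m=5, b_xy_true=0.0, n_exp=10_000, n_out=10_000,
                                 pleiotropy=[(2, 0.5)], noise_free=True, seed=1)
        pair = simulate_instruments(scn)
        assert pair.df["bzy"].iloc[2] == pytest.approx(0.5)
        assert (pair.df["bzy"].drop(index=2) == 0).all()

    def test_overlap_rho_correlates_errors(self):
        scn = InstrumentScenario(m=20_000, b_xy_true=0.0, n_exp=10_000,
                                 n_out=10_000, maf_range=(0.3, 0.3),
                                 overlap_rho=0.8, seed=2)
        pair = simulate_instruments(scn)
        # with b_xy_true = 0 the outcome z IS the outcome error (unit SD);
        # the exposure z is true-z plus a unit-SD error independent of the
        # true effect, so cov(z_x, e_y) estimates rho directly
        z_x = (pair.df["bzx"] / pair.df["se_zx"]).to_numpy()
        e_y = (pair.df["bzy"] / pair.df["se_zy"]).to_numpy()
        rho_hat = np.cov(z_x, e_y)[0, 1]
        assert rho_hat == pytest.approx(0.8, abs=0.05)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            InstrumentScenario(m=0, b_xy_true=0, n_exp=100, n_out=100)
        with pytest.raises(ValueError):
            InstrumentScenario(m=5, b_xy_true=0, n_exp=100, n_out=100,
                               pleiotropy=[(9, 1.0)])
        with pytest.raises(ValueError):
            InstrumentScenario(m=5, b_xy_true=0, n_exp=100, n_out=100,
                               maf_range=(0.0, 0.6))


class TestRegionSimulation:
    def test_null_region_rarely_significant(self):
        scn = RegionScenario(n_snps=500, rho=0.0, causal_1=0, causal_2=0,
                             lambda_1=0.0, lambda_2=0.0, n1=10_000, n2=10_000,
                             seed=4)
        t1, t2, _ = simulate_region(scn)
        z = np.abs(t1.df["beta"] / t1.df["se"])
        assert z.max() < 5.45  # P(any |z|>5.45) ~ 500 * 4e-8 << 1e-4

    def test_marginal_z_unit_variance_when_independent(self):
        zs = []
        for seed in range(100):
            scn = RegionScenario(n_snps=100, rho=0.0, causal_1=0, causal_2=0,
                                 lambda_1=0.0, lambda_2=0.0, n1=10_000,
                                 n2=10_000, seed=seed)
            t1, _, _ = simulate_region(scn)
            zs.append((t1.df["beta"] / t1.df["se"]).to_numpy())
        z = np.concatenate(zs)
        assert len(z) == 10_000
        assert 0.9 < z.var() < 1.1

    def test_empirical_correlation_converges_to_R(self):
        n_snps, reps = 30, 10_000
        rng = np.random.default_rng(0)
        from mrcoloc.ld import make_ar1_ld as ar1
        R = ar1(n_snps, 0.8).r
        chol = np.linalg.cholesky(R)
        draws = (chol @ rng.standard_normal((n_snps, reps)))
        emp = np.corrcoef(draws)
        assert np.abs(emp - R).max() < 0.05

    def test_null_pvalues_uniform(self):
        scn = RegionScenario(n_snps=10_000, rho=0.0, causal_1=0, causal_2=0,
                             lambda_1=0.0, lambda_2=0.0, n1=10_000, n2=10_000,
                             seed=9)
        t1, _, _ = simulate_region(scn)
        ks = stats.kstest(t1.df["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_causal_mean_is_ld_projected(self):
        # average over replicates of z at the causal and a neighbor
        z_c, z_n = [], []
        for seed in range(300):
            scn = RegionScenario(n_snps=21, rho=0.9, causal_1=10, causal_2=10,
                                 lambda_1=8.0, lambda_2=8.0, n1=10_000,
                                 n2=10_000, seed=seed)
            t1, _, _ = simulate_region(scn)
            z = (t1.df["beta"] / t1.df["se"]).to_numpy()
            z_c.append(z[10])
            z_n.append(z[12])
        assert np.mean(z_c) == pytest.approx(8.0, abs=3 * np.std(z_c) / np.sqrt(300))
        assert np.mean(z_n) == pytest.approx(8.0 * 0.81,
                                             abs=3 * np.std(z_n) / np.sqrt(300))

    def test_positions_evenly_spaced(self):
        scn = scenario_preset("coloc_shared", seed=1)
        t1, _, ld = simulate_region(scn)
        assert len(ld) == 1001
        assert np.unique(np.diff(t1.df["pos"]))[0] == 1000


class TestPresets:
    @pytest.mark.parametrize("name,b_xy,m,n_out", [
        ("table3_bft", 0.13, 115, 39_323),
        ("table3_lmdep", 0.35, 113, 24_215),
        ("table3_aff", -3.24, 106, 5_707),
        ("table3_nsb", -0.05, 112, 17_077),
    ])
    def test_outcome_presets_parameterized_from_study(self, name, b_xy, m, n_out):
        scn = scenario_preset(name)
        assert scn.b_xy_true == b_xy
        assert scn.m == m
        assert scn.n_exp == 20_555
        assert scn.n_out == n_out

    def test_bft_pleiotropy_preset_embeds_published_rows(self):
        scn = scenario_preset("table2_bft_pleio")
        planted = [(r[0], r[2]) for r in scn.planted]
        assert planted == [(-3.28, -0.14), (-5.47, -0.21), (-3.26, -0.17),
                           (2.33, 0.14)]
        assert scn.noise_free

    def test_lmdep_pleiotropy_preset_has_two_rows(self):
        scn = scenario_preset("table2_lmdep_pleio")
        assert len(scn.planted) == 2

    def test_null_preset(self):
        scn = scenario_preset("null")
        assert scn.b_xy_true == 0.0
        assert scn.pleiotropy == []

    def test_coloc_presets_shared_vs_distinct(self):
        shared = scenario_preset("coloc_shared")
        distinct = scenario_preset("coloc_distinct")
        assert shared.shared and not distinct.shared
        assert abs(distinct.causal_1 - distinct.causal_2) == 200
        for scn in (shared, distinct):
            assert (scn.n_snps, scn.rho, scn.lambda_1) == (1001, 0.9, 12.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            scenario_preset("table3_nope")

    def test_scenario_yaml_round_trip(self, tmp_path):
        scn = scenario_preset("table2_lmdep_pleio", seed=3)
        f = tmp_path / "scn.yaml"
        scn.to_yaml(f)
        back = scenario_from_yaml(f)
        assert back == scn
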