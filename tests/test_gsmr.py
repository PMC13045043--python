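"""Ratio estimates, the LD-aware IVW combination and HEIDI-outlier filtering."""

import numpy as np
import pandas as pd
import pytest

from mrcoloc import (GsmrModel, LDMatrix, assemble_instruments, build_v,
                     heidi_outlier, ivw_fit, ratio_estimates, run_gsmr,
                     scenario_preset, simulate_instruments)
from mrcoloc.gsmr import DegenerateInstrumentError, MrStudyResult
from mrcoloc.instruments import InsufficientInstrumentsError
from mrcoloc.pipeline import run_preset_chain
from mrcoloc.simulate import identity_ld
from mrcoloc.sumstats import two_sided_p

from test_instruments import make_pair


def iset_from(bzx, se_zx, bzy, se_zy, ld=None):
    m = len(bzx)
    pair = make_pair([f"s{i}" for i in range(m)], bzx=bzx, se_zx=se_zx,
                     bzy=bzy, se_zy=se_zy)
    return assemble_instruments(pair, ld or identity_ld(pair.df["snp"]),
                                min_instruments=1)


class TestRatioEstimates:
    def test_published_row_delta_method(self):
        # exposure effect -3.28 (0.58), outcome effect -0.14 (0.03)
        iset = iset_from([-3.28], [0.58], [-0.14], [0.03])
        r = ratio_estimates(iset)
        assert r["b_xy"].iloc[0] == pytest.approx(0.042683, rel=1e-4)
        assert np.sqrt(r["var"].iloc[0]) == pytest.approx(0.011859, rel=1e-3)

    def test_zero_outcome_effect(self):
        iset = iset_from([0.5], [0.1], [0.0], [0.02])
        r = ratio_estimates(iset)
        assert r["b_xy"].iloc[0] == 0.0
        assert r["var"].iloc[0] == pytest.approx(0.02 ** 2 / 0.25)

    def test_identity_case(self):
        s = 0.03
        iset = iset_from([0.4], [s], [0.4], [s])
        r = ratio_estimates(iset)
        assert r["b_xy"].iloc[0] == 1.0
        assert r["var"].iloc[0] == pytest.approx(2 * s ** 2 / 0.16)

    def test_zero_exposure_effect_raises(self):
        iset = iset_from([0.0], [0.1], [0.1], [0.02])
        with pytest.raises(DegenerateInstrumentError, match="s0"):
            ratio_estimates(iset)


class TestBuildV:
    def test_identity_ld_gives_diagonal(self):
        iset = iset_from([0.3, 0.4], [0.02, 0.03], [0.1, 0.2], [0.01, 0.02])
        r = ratio_estimates(iset)
        v, info = build_v(iset, r)
        assert v[0, 1] == 0.0
        np.testing.assert_allclose(np.diag(v), r["var"], rtol=1e-12)
        assert not info["ridged"]

    def test_offdiagonal_formula_consistent_with_diagonal_at_r1(self):
        # the i=j limit of the off-diagonal expression must equal V_ii
        bzx, se_zx, bzy, se_zy = 0.3, 0.02, 0.12, 0.015
        iset = iset_from([bzx], [se_zx], [bzy], [se_zy])
        r = ratio_estimates(iset)
        b_xy = r["b_xy"].iloc[0]
        off = 1.0 * (se_zy * se_zy + b_xy * b_xy * se_zx * se_zx) / (bzx * bzx)
        assert off == pytest.approx(r["var"].iloc[0], rel=1e-12)

    def test_two_instrument_plugin(self):
        s = 0.01
        ld = LDMatrix(["s0", "s1"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        iset = iset_from([0.3, 0.4], [0.02, 0.03], [0.0, 0.0], [s, s], ld=ld)
        r = ratio_estimates(iset)
        v, _ = build_v(iset, r)
        assert v[0, 1] == pytest.approx(0.5 * s ** 2 / (0.3 * 0.4), rel=1e-12)

    def test_near_singular_gets_ridge(self):
        ld = LDMatrix(["s0", "s1"], np.array([[1.0, 1.0], [1.0, 1.0]]),
                      validate=False)
        iset = iset_from([0.3, 0.3], [0.02, 0.02], [0.1, 0.1], [0.01, 0.01],
                         ld=ld)
        r = ratio_estimates(iset)
        v, info = build_v(iset, r)
        assert info["ridged"]
        assert np.linalg.eigvalsh(v).min() > 0


class TestIvwFit:
    def test_single_instrument_reduces_to_ratio(self):
        iset = iset_from([-3.28], [0.58], [-0.14], [0.03])
        r = ratio_estimates(iset)
        v, _ = build_v(iset, r)
        est, se, p = ivw_fit(r, v)
        assert est == pytest.approx(r["b_xy"].iloc[0])
        assert se == pytest.approx(np.sqrt(r["var"].iloc[0]))

    def test_identity_v_hand_algebra(self):
        r = pd.DataFrame({"snp": ["a", "b"], "b_xy": [1.0, 3.0],
                          "var": [1.0, 1.0]})
        est, se, _ = ivw_fit(r, np.eye(2))
        assert est == pytest.approx(2.0)
        assert se ** 2 == pytest.approx(0.5)

    def test_correlated_v_hand_algebra(self):
        r = pd.DataFrame({"snp": ["a", "b"], "b_xy": [1.0, 3.0],
                          "var": [1.0, 1.0]})
        v = np.array([[1.0, 0.5], [0.5, 1.0]])
        est, se, _ = ivw_fit(r, v)
        assert est == pytest.approx(2.0)
        assert se ** 2 == pytest.approx(0.75)

    def test_diagonal_v_equals_classic_weighted_mean(self, rng):
        m = 40
        b = rng.normal(0.2, 0.5, m)
        var = rng.uniform(0.01, 1.0, m)
        r = pd.DataFrame({"snp": [f"s{i}" for i in range(m)], "b_xy": b,
                          "var": var})
        est, se, _ = ivw_fit(r, np.diag(var))
        w = 1.0 / var
        assert est == pytest.approx(np.sum(w * b) / np.sum(w), rel=1e-10)
        assert se == pytest.approx(1.0 / np.sqrt(np.sum(w)), rel=1e-10)

    def test_p_is_two_sided_normal_of_z(self):
        r = pd.DataFrame({"snp": ["a"], "b_xy": [0.3], "var": [0.01]})
        est, se, p = ivw_fit(r, np.array([[0.01]]))
        assert p == pytest.approx(float(two_sided_p(est / se)), abs=1e-12)


class TestEquivariance:
    def test_negating_outcome_negates_estimate(self):
        pair = simulate_instruments(scenario_preset("table3_bft", seed=5))
        res1 = run_preset_chain(pair)
        flipped = pair.df.copy()
        flipped["bzy"] = -flipped["bzy"]
        pair2 = type(pair)(pair.exposure_trait, pair.outcome_trait, flipped)
        res2 = run_preset_chain(pair2)
        assert res2.b_xy == pytest.approx(-res1.b_xy, rel=1e-12)
        assert res2.se == pytest.approx(res1.se, rel=1e-12)

    def test_scaling_exposure_inversely_scales_estimate(self):
        pair = simulate_instruments(scenario_preset("table3_lmdep", seed=5))
        res1 = run_preset_chain(pair)
        c = 2.5
        scaled = pair.df.copy()
        scaled["bzx"] = c * scaled["bzx"]
        scaled["se_zx"] = c * scaled["se_zx"]
        pair2 = type(pair)(pair.exposure_trait, pair.outcome_trait, scaled)
        res2 = run_preset_chain(pair2)
        assert res2.b_xy == pytest.approx(res1.b_xy / c, rel=1e-12)


class TestHeidi:
    def test_identical_ratios_no_exclusion(self):
        m = 12
        bzx = np.linspace(0.2, 0.5, m)
        iset = iset_from(bzx, np.full(m, 0.02), 0.3 * bzx, np.full(m, 0.01))
        kept, report = heidi_outlier(iset)
        assert report.n_excluded == 0
        assert len(kept) == m

    def test_reference_is_strongest_exposure_association(self):
        m = 12
        bzx = np.linspace(0.2, 0.5, m)
        iset = iset_from(bzx, np.full(m, 0.02), 0.3 * bzx, np.full(m, 0.01))
        _, report = heidi_outlier(iset)
        assert report.reference_variant == f"s{m - 1}"

    def test_bft_planted_pleiotropy_exactly_four_excluded(self):
        pair = simulate_instruments(scenario_preset("table2_bft_pleio", seed=0))
        iset = assemble_instruments(pair, identity_ld(pair.df["snp"]))
        kept, report = heidi_outlier(iset, alpha=0.01)
        assert report.n_excluded == 4
        assert set(report.excluded["snp"]) == {
            "1:158058352", "1:162719373", "1:162899224", "7:29132104"}
        assert len(kept) == 115

    def test_lmdep_planted_pleiotropy_exactly_two_excluded(self):
        pair = simulate_instruments(scenario_preset("table2_lmdep_pleio", seed=0))
        iset = assemble_instruments(pair, identity_ld(pair.df["snp"]))
        kept, report = heidi_outlier(iset, alpha=0.01)
        assert report.n_excluded == 2
        assert set(report.excluded["snp"]) == {"7:21813401", "7:33305936"}

    def test_noise_free_fit_recovers_planted_effect_exactly(self):
        pair = simulate_instruments(scenario_preset("table2_bft_pleio", seed=0))
        iset = assemble_instruments(pair, identity_ld(pair.df["snp"]))
        res = GsmrModel(iset).fit()
        assert res.b_xy == pytest.approx(0.13, rel=1e-9)
        assert res.m_used == 115

    def test_specificity_near_alpha_on_clean_instruments(self):
        # expected false exclusions ~ alpha * (m - 1) per replicate
        total_excluded, total_tested = 0, 0
        for seed in range(60):
            pair = simulate_instruments(scenario_preset("table3_bft", seed=seed))
            iset = assemble_instruments(pair, identity_ld(pair.df["snp"]))
            _, report = heidi_outlier(iset, alpha=0.01)
            total_excluded += report.n_excluded
            total_tested += len(iset) - 1
        rate = total_excluded / total_tested
        se = np.sqrt(0.01 * 0.99 / total_tested)
        assert rate == pytest.approx(0.01, abs=3 * se)

    def test_exclusion_below_minimum_raises_with_report(self):
        m = 10
        bzx = np.full(m, 0.3)
        bzy = np.full(m, 0.3 * 0.2)
        bzy[0] = 2.0  # gross outlier
        iset = iset_from(bzx, np.full(m, 0.01), bzy, np.full(m, 0.005))
        with pytest.raises(InsufficientInstrumentsError) as exc:
            heidi_outlier(iset, alpha=0.01, min_instruments=10)
        assert exc.value.report.n_excluded >= 1


class TestStudyLevel:
    def test_bonferroni_four_outcomes(self):
        pairs = {f"Y{k}": simulate_instruments(
            scenario_preset("table3_bft", seed=k)) for k in range(4)}
        fits = {t: run_preset_chain(p) for t, p in pairs.items()}
        study = MrStudyResult("X", fits, bonferroni_alpha=0.05 / 4)
        assert study.bonferroni_alpha == 0.0125
        frame = study.to_frame()
        assert set(frame.columns) >= {"trait", "snp_out", "snp_index", "b_xy",
                                      "se", "p", "n_ivs", "significant"}

    def test_run_gsmr_single_outcome_alpha(self):
        pair = simulate_instruments(scenario_preset("table3_bft", seed=2))
        exposure = pair.exposure_table()
        outcome = pair.outcome_table()
        ld = identity_ld(pair.df["snp"])
        res = run_gsmr(exposure, [outcome], ld)
        assert res.bonferroni_alpha == 0.05
        assert res.fits["BFT"].b_xy == pytest.approx(0.13, abs=0.05)

    def test_summary_mentions_key_quantities(self):
        pair = simulate_instruments(scenario_preset("table3_bft", seed=2))
        res = run_preset_chain(pair)
        text = res.summary()
        assert "b_xy" in text and "HEIDI" in text and "95% CI" in text
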