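"""CPMG dispersion: R2,eff, duplicate errors, forward models, AICc fits."""

import numpy as np
import pytest

from chexfit.cpmg import (
    DEFAULT_NU_GRID,
    aicc,
    carver_richards,
    compute_r2eff,
    estimate_r2eff_errors,
    fit_global_dispersion,
    fit_residue_dispersion,
    profiles_from_dataset,
    r2eff_exact,
    r2eff_propagated,
    simulate_dispersion,
)
from chexfit.datamodel import CPMGProfile, ResidueID, TwoStateModel, nitrogen_hz_per_ppm
from chexfit.synthetic import SCENARIOS, gen_cpmg_dataset, residue_set


def make_profile(r2eff, sigma=0.3, nu=None, rid_number=103):
    nu = DEFAULT_NU_GRID if nu is None else nu
    return CPMGProfile(
        residue=ResidueID("A", rid_number, "GLY"),
        nu_cpmg=nu, r2eff=np.asarray(r2eff, dtype=float),
        r2eff_err=np.full(len(nu), sigma))


class TestComputeR2eff:
    def test_identity_point(self):
        assert compute_r2eff(1.0, 1.0, 0.04) == 0.0

    @pytest.mark.parametrize("ratio,expected", [
        (np.exp(-1.0), 25.0),          # -ln(e^-1)/0.04
        (0.2, 40.23594781),            # -ln(0.2)/0.04
    ])
    def test_closed_form(self, ratio, expected):
        assert compute_r2eff(ratio, 1.0, 0.04) == pytest.approx(expected)

    def test_nonpositive_intensity_censored(self):
        assert np.isnan(compute_r2eff(-0.1, 1.0, 0.04))


class TestDuplicateErrors:
    def test_identical_duplicates_hit_floor(self):
        nu = np.array([50.0, 50.0, 750.0])
        sigma = estimate_r2eff_errors(nu, np.array([10.0, 10.0, 8.0]),
                                      floor=0.1)
        assert sigma == 0.1

    def test_single_pair(self):
        nu = np.array([50.0, 50.0])
        sigma = estimate_r2eff_errors(nu, np.array([10.0, 11.0]), floor=0.0)
        assert sigma == pytest.approx(np.sqrt(0.5), abs=1e-9)   # 0.707

    def test_two_pairs_pooled(self):
        nu = np.array([50.0, 50.0, 750.0, 750.0])
        sigma = estimate_r2eff_errors(
            nu, np.array([10.0, 11.0, 8.0, 8.0]), floor=0.0)
        assert sigma == pytest.approx(0.5, abs=1e-9)   # sqrt((0.5+0)/2)

    def test_no_duplicates_warns_and_uses_default(self):
        with pytest.warns(UserWarning, match="no duplicate"):
            sigma = estimate_r2eff_errors(np.array([50.0, 100.0]),
                                          np.array([10.0, 9.0]), floor=0.4)
        assert sigma == 0.4


class TestForwardModels:
    def test_no_excited_state_is_flat(self):
        m = TwoStateModel(kex=1000.0, p_es=0.0, delta_omega_ppm=3.0, r2_0=12.0)
        np.testing.assert_allclose(simulate_dispersion(m), 12.0)

    def test_zero_shift_difference_is_flat(self):
        m = TwoStateModel(kex=1000.0, p_es=0.05, delta_omega_ppm=0.0, r2_0=9.0)
        np.testing.assert_allclose(simulate_dispersion(m), 9.0)

    def test_fast_exchange_luz_meiboom_limit(self):
        # Rex ~ pG pE dw^2 / kex = 0.97*0.03*500^2/5000 = 1.455 1/s
        dw_ppm = 500.0 / (2 * np.pi * nitrogen_hz_per_ppm(800.13))
        m = TwoStateModel(kex=5000.0, p_es=0.03, delta_omega_ppm=dw_ppm,
                          r2_0=10.0)
        curve = simulate_dispersion(m, np.array([10.0, 1e5]))
        assert curve[0] - curve[1] == pytest.approx(1.455, rel=0.05)

    def test_exact_matches_propagator_on_regime_grid(self):
        """Closed form vs numerical propagation <= 0.5 1/s across regimes."""
        nu = DEFAULT_NU_GRID
        worst = 0.0
        for kex in (100.0, 600.0, 2000.0, 6000.0):
            for p_es in (0.01, 0.05, 0.1):
                for dw_ppm in (0.5, 2.0, 6.0):
                    dw = 2 * np.pi * dw_ppm * nitrogen_hz_per_ppm(800.13)
                    a = r2eff_exact(nu, 0.04, 10.0, kex, p_es, dw)
                    b = r2eff_propagated(nu, 0.04, 10.0, kex, p_es, dw)
                    worst = max(worst, float(np.max(np.abs(a - b))))
        assert worst <= 0.5

    def test_carver_richards_close_in_fast_exchange(self):
        dw = 2 * np.pi * 2.0 * nitrogen_hz_per_ppm(800.13)
        a = carver_richards(DEFAULT_NU_GRID, 10.0, 5000.0, 0.02, dw)
        b = r2eff_exact(DEFAULT_NU_GRID, 0.04, 10.0, 5000.0, 0.02, dw)
        assert np.max(np.abs(a - b)) < 0.3

    def test_monotone_non_increasing_in_nu(self):
        # fast/intermediate regimes only: in slow exchange dispersion curves
        # genuinely oscillate at low refocusing frequencies.  Exact model on
        # the acquisition grid (integer echo counts); the smooth CR72
        # approximation additionally checked on a dense grid.
        dense = np.linspace(50, 2000, 60)
        for kex in (1000.0, 2000.0, 6000.0):
            for dw_ppm in (1.0, 4.0):
                m = TwoStateModel(kex=kex, p_es=0.03,
                                  delta_omega_ppm=dw_ppm, r2_0=10.0)
                curve = simulate_dispersion(m, DEFAULT_NU_GRID)
                assert np.all(np.diff(curve) <= 1e-6)
                dw = 2 * np.pi * dw_ppm * nitrogen_hz_per_ppm(800.13)
                smooth = carver_richards(dense, 10.0, kex, 0.03, dw)
                assert np.all(np.diff(smooth) <= 1e-6)


class TestAicc:
    def test_closed_form(self):
        # 10 ln(1) + 2*2 + 2*2*3/7 = 5.714...
        assert aicc(10.0, 10, 2) == pytest.approx(5.714, abs=1e-3)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(1.0, 5, 4)


class TestResidueFit:
    def test_flat_profile_selects_no_exchange(self):
        rng = np.random.default_rng(5)
        selected = []
        for trial in range(20):
            y = 10.0 + rng.normal(0, 0.3, len(DEFAULT_NU_GRID))
            r = fit_residue_dispersion(make_profile(y), seed=trial)
            selected.append(r.model)
        assert selected.count("no-exchange") >= 19

    def test_dispersive_profile_recovers_rex(self):
        # strong dispersion, Rex ~ 40 1/s as seen for the most mobile sites
        m = TwoStateModel(kex=1240.0, p_es=0.04, delta_omega_ppm=7.0, r2_0=12.0)
        truth = simulate_dispersion(m)
        rex_truth = truth[0] - truth[-1]
        assert rex_truth > 30.0
        rng = np.random.default_rng(3)
        y = truth + rng.normal(0, 0.3, len(truth))
        r = fit_residue_dispersion(make_profile(y), seed=2)
        assert r.model == "two-site"
        assert abs(r.r_ex - rex_truth) < 3.0

    def test_reports_both_aicc_values(self):
        y = simulate_dispersion(TwoStateModel(kex=800.0, p_es=0.03,
                                              delta_omega_ppm=3.0, r2_0=10.0))
        r = fit_residue_dispersion(make_profile(y), seed=0)
        assert set(r.aicc) == {"no-exchange", "two-site"}
        assert r.r_ex >= 0.0

    def test_needs_six_distinct_frequencies(self):
        nu = np.array([50.0, 100.0, 200.0, 350.0, 500.0])
        with pytest.raises(ValueError, match=">= 6"):
            fit_residue_dispersion(make_profile(np.full(5, 10.0), nu=nu))


class TestGlobalFit:
    def _noiseless_profiles(self, kex=1240.0, p_es=0.03, n_res=4, seed=0):
        cfg = SCENARIOS["tan-291K"].replace(
            residues=residue_set("tan")[:n_res], kex=kex, p_es=p_es,
            noise=0.0, seed=seed)
        raw, truth = gen_cpmg_dataset(cfg)
        return profiles_from_dataset(raw, cfg.t_cp, cfg.field_mhz,
                                     cfg.temperature), truth

    def test_noiseless_recovery_to_one_percent(self):
        profiles, truth = self._noiseless_profiles()
        g = fit_global_dispersion(profiles, seed=1)
        assert g.kex == pytest.approx(truth["kex"], rel=0.01)
        assert g.p_es == pytest.approx(truth["p_es"], rel=0.01)
        for rid in g.residues:
            dw_true = abs(truth["residues"][str(rid)]["delta_omega_ppm"])
            assert g.dw_ppm[rid][0] == pytest.approx(dw_true, rel=0.02)

    def test_single_residue_global_equals_residue_fit(self):
        profiles, _ = self._noiseless_profiles(n_res=1)
        g = fit_global_dispersion(profiles, seed=3)
        r = fit_residue_dispersion(profiles[0], seed=3)
        assert r.model == "two-site"
        assert g.kex == pytest.approx(r.kex, rel=1e-6)
        assert g.p_es == pytest.approx(r.p_es, rel=1e-6)

    def test_degenerate_single_residue_warns(self):
        profiles, _ = self._noiseless_profiles(n_res=1)
        with pytest.warns(UserWarning, match="degenerate"):
            fit_global_dispersion(profiles, seed=0)

    def test_mixed_conditions_rejected(self):
        profiles, _ = self._noiseless_profiles(n_res=2)
        profiles[1].temperature = 278.0
        with pytest.raises(ValueError, match="share temperature"):
            fit_global_dispersion(profiles)
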