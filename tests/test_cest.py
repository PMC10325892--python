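"""Bloch-McConnell CEST simulation, dip detection and fitting."""

import numpy as np
import pytest
from scipy.linalg import expm

from chexfit.cest import (
    DEFAULT_OFFSETS,
    _bm_generator,
    _propagate_z,
    detect_dips,
    fit_cest,
    fit_cest_group,
    simulate_cest,
)
from chexfit.datamodel import CESTProfile, ResidueID, TwoStateModel
from chexfit.synthetic import SCENARIOS, gen_cest_dataset


def make_model(kex=60.0, p_es=0.05, d_gs=120.0, d_es=115.0, r1=1.5, r2=10.0):
    return TwoStateModel(kex=kex, p_es=p_es, delta_omega_ppm=d_es - d_gs,
                         r2_0=r2, r1=r1, delta_gs_ppm=d_gs)


def as_profile(curve, offsets=DEFAULT_OFFSETS, b1=15.0, err=0.0,
               rid_number=145):
    return CESTProfile(ResidueID("A", rid_number, "VAL"),
                       offsets=offsets, intensities=curve,
                       errors=np.full(len(offsets), err), b1_hz=b1)


class TestSimulate:
    def test_zero_b1_profile_is_flat_at_r1_decay(self):
        curve = simulate_cest(make_model(), b1_hz=1e-9, t_sat=0.4)
        assert np.ptp(curve) < 1e-10
        assert curve[0] == pytest.approx(np.exp(-1.5 * 0.4), abs=1e-8)

    def test_single_state_saturation_dip_at_ground_state(self):
        m = make_model(p_es=0.0, d_gs=118.0)
        curve = simulate_cest(m, b1_hz=30.0, t_sat=2.0)
        dip = DEFAULT_OFFSETS[np.argmin(curve)]
        assert abs(dip - 118.0) <= np.abs(DEFAULT_OFFSETS[1] - DEFAULT_OFFSETS[0])
        assert curve.min() < 0.05      # essentially saturated on resonance

    def test_slow_exchange_minima_at_both_state_shifts(self):
        """Dense-grid oracle: numerical minima sit at delta_GS and delta_ES."""
        m = make_model(kex=60.0, p_es=0.05, d_gs=120.0, d_es=115.0)
        dense = np.linspace(125.0, 110.0, 601)
        curve = simulate_cest(m, dense, b1_hz=15.0)
        # local minima on the dense grid
        interior = (curve[1:-1] < curve[:-2]) & (curve[1:-1] < curve[2:])
        minima = dense[1:-1][interior]
        assert any(abs(x - 120.0) < 0.1 for x in minima)
        assert any(abs(x - 115.0) < 0.1 for x in minima)

    def test_detailed_balance_stationary_populations(self):
        """Exchange-only dynamics relaxes z to (p_GS, p_ES) partitioning."""
        m = make_model(kex=500.0, p_es=0.04, r1=0.0, r2=0.0)
        K = _bm_generator(np.array([0.0]), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                          m.k_ge, m.k_eg)
        # start fully on the ground state; long-time z split is (1-p, p)
        m0 = np.array([0, 0, 1.0, 0, 0, 0.0])
        mt = expm(K[0] * 5.0) @ m0
        assert mt[2] == pytest.approx(1 - 0.04, abs=1e-12)
        assert mt[5] == pytest.approx(0.04, abs=1e-12)

    def test_mirror_symmetry(self):
        m = make_model(d_gs=120.0, d_es=115.0)
        mirrored = make_model(d_gs=120.0, d_es=125.0)
        offs = np.linspace(130, 110, 41)
        a = simulate_cest(m, offs)
        b = simulate_cest(mirrored, 2 * 120.0 - offs)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_eig_path_matches_expm(self):
        m = make_model(kex=572.0, p_es=0.03, d_gs=118.0, d_es=121.0)
        K = _bm_generator(np.asarray(DEFAULT_OFFSETS) * 81.1, 118.0 * 81.1,
                          121.0 * 81.1, 30.0, m.r1, m.r2_0, m.r2_0,
                          m.k_ge, m.k_eg)
        fast = _propagate_z(K, 0.4, np.array([0, 0, 0.97, 0, 0, 0.03]))
        slow = np.array([(expm(k * 0.4) @ [0, 0, 0.97, 0, 0, 0.03])[2]
                         for k in K])
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_nonfinite_parameters_rejected(self):
        m = make_model()
        m.kex = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            simulate_cest(m)


class TestDetectDips:
    def test_single_dip(self):
        curve = simulate_cest(make_model(p_es=0.0, d_gs=118.0), b1_hz=30.0)
        dips = detect_dips(as_profile(curve, b1=30.0))
        step = abs(DEFAULT_OFFSETS[1] - DEFAULT_OFFSETS[0])
        assert len(dips) >= 1 and abs(dips[0] - 118.0) <= step

    def test_two_dips_major_first(self):
        curve = simulate_cest(make_model(), b1_hz=15.0)
        dips = detect_dips(as_profile(curve))
        assert len(dips) >= 2
        assert abs(dips[0] - 120.0) < 0.6
        assert abs(dips[1] - 115.0) < 0.6

    def test_pure_noise_rarely_triggers(self):
        rng = np.random.default_rng(11)
        empty = 0
        for _ in range(100):
            curve = 0.85 + rng.normal(0, 0.01, 64)
            if not detect_dips(as_profile(curve, err=0.01)):
                empty += 1
        assert empty >= 95

    def test_needs_enough_offsets(self):
        with pytest.raises(ValueError, match=">= 16"):
            detect_dips(as_profile(np.ones(8), offsets=np.linspace(120, 110, 8)))


class TestFitCest:
    def _profiles(self, noise=0.0, seed=0, noise_seed=None, n_res=1):
        base = SCENARIOS["tan-cest-283K"]
        cfg = base.replace(seed=seed, noise=noise, noise_seed=noise_seed,
                           residues=base.residues[:n_res])
        profs, truth = gen_cest_dataset(cfg)
        by_res = {}
        for p in profs:
            by_res.setdefault(p.residue, []).append(p)
        return list(by_res.values()), truth

    def test_noiseless_two_b1_recovery_within_one_percent(self):
        groups, truth = self._profiles()
        r = fit_cest(groups[0], seed=0)
        assert r.kex == pytest.approx(truth["kex"], rel=0.01)
        assert r.p_es == pytest.approx(truth["p_es"], rel=0.01)
        t = truth["residues"][str(groups[0][0].residue)]
        assert r.delta_gs_ppm == pytest.approx(t["delta_gs_ppm"], abs=0.05)
        assert r.dw_ppm == pytest.approx(t["delta_omega_ppm"], abs=0.05)

    @pytest.mark.parametrize("kex,p_es,dw", [
        (100.0, 0.05, 4.0), (572.0, 0.03, -3.0), (2000.0, 0.1, 6.0)])
    def test_noiseless_recovery_across_regimes(self, kex, p_es, dw):
        m = make_model(kex=kex, p_es=p_es, d_gs=117.0, d_es=117.0 + dw)
        profs = [as_profile(simulate_cest(m, b1_hz=b1), b1=b1)
                 for b1 in (15.0, 30.0)]
        r = fit_cest(profs, seed=0)
        assert r.kex == pytest.approx(kex, rel=0.01)
        assert r.p_es == pytest.approx(p_es, rel=0.01)
        assert r.dw_ppm == pytest.approx(dw, abs=0.05)

    def test_no_excited_state_flagged_degenerate(self):
        m = make_model(p_es=0.0, d_gs=118.0)
        profs = [as_profile(simulate_cest(m, b1_hz=b1), b1=b1)
                 for b1 in (15.0, 30.0)]
        r = fit_cest(profs, seed=0)
        assert any("single dip" in f or "pinned" in f for f in r.flags)

    def test_group_of_one_equals_single_fit(self):
        groups, _ = self._profiles()
        single = fit_cest(groups[0], seed=0)
        group = fit_cest_group(groups, seed=0)
        assert group.kex == pytest.approx(single.kex, rel=1e-6)
        assert group.p_es == pytest.approx(single.p_es, rel=1e-6)

    def test_group_shares_kinetics_noiselessly(self):
        groups, truth = self._profiles(n_res=3)
        g = fit_cest_group(groups, seed=0)
        assert g.kex == pytest.approx(truth["kex"], rel=0.02)
        assert g.p_es == pytest.approx(truth["p_es"], rel=0.02)
        assert len(g.chi2_per_residue) == 3

    def test_conflicting_kinetics_exposed_per_residue(self):
        fast = make_model(kex=2000.0, p_es=0.05, d_gs=112.0, d_es=116.0)
        slow = make_model(kex=300.0, p_es=0.05, d_gs=122.0, d_es=118.0)
        groups = []
        for i, m in enumerate((slow, slow, fast)):
            groups.append([as_profile(simulate_cest(m, b1_hz=b1), b1=b1,
                                      rid_number=101 + i)
                           for b1 in (15.0, 30.0)])
        g = fit_cest_group(groups, seed=0)
        chi2 = {rid.number: v for rid, v in g.chi2_per_residue.items()}
        # the misfitting fast residue carries almost all the chi-square
        assert chi2[103] > 10 * max(chi2[101], chi2[102], 1e-6)
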