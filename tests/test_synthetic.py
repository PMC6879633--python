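"""Generators: determinism, zero-noise exactness, noise calibration, CTMC laws."""

import numpy as np
import pytest

from confex.constants import R_KCAL, T_REF
from confex.dimer import monomer_fraction
from confex.exceptions import InvalidModelError
from confex.synthetic import (
    CTMC_STATES,
    DEFAULT_MIXING_TIMES,
    DEFAULT_TEMPERATURES,
    DimerCoupledRateLaw,
    SynthSpec,
    arrhenius_rate,
    ctmc_stationary,
    dimer_coupled_rate,
    gen_backbone_ensemble,
    gen_denaturation,
    gen_rate_series,
    gen_rotamer_traj,
    gen_titration,
    gen_zz_dataset,
    single_dihedral_rate_matrix,
)
from confex.zz import ZZParams, predict_zz

TRUTH = ZZParams(2.0, 4.0, 1.5, 1.8, 1.0, 0.6)


class TestSpecValidation:
    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidModelError):
            SynthSpec(1, 0.0, [], TRUTH)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidModelError):
            SynthSpec(1, -0.1, [0.0, 0.1], TRUTH)


class TestZZGenerator:
    def test_zero_noise_equals_model(self):
        ds = gen_zz_dataset(SynthSpec(1, 0.0, DEFAULT_MIXING_TIMES, TRUTH))
        aa, bb, ab, ba = predict_zz(TRUTH, ds.mixing_times)
        assert np.array_equal(ds.I_AA, aa) and np.array_equal(ds.I_BB, bb)
        assert np.array_equal(ds.I_AB, ab) and np.array_equal(ds.I_BA, ba)

    def test_seed_determinism(self):
        a = gen_zz_dataset(SynthSpec(7, 0.02, DEFAULT_MIXING_TIMES, TRUTH))
        b = gen_zz_dataset(SynthSpec(7, 0.02, DEFAULT_MIXING_TIMES, TRUTH))
        assert np.array_equal(a.I_AA, b.I_AA) and np.array_equal(a.I_BA, b.I_BA)

    def test_residual_noise_calibration(self):
        """sd 0.02, 1000 mixing times: sample sd of residuals in [0.018, 0.022]."""
        times = np.linspace(0.0, 0.4, 1000)
        ds = gen_zz_dataset(SynthSpec(5, 0.02, times, TRUTH))
        model = np.stack(predict_zz(TRUTH, times))
        resid = np.stack([ds.I_AA, ds.I_BB, ds.I_AB, ds.I_BA]) - model
        assert 0.018 <= resid.std() <= 0.022

    def test_too_few_mixing_times(self):
        with pytest.raises(InvalidModelError):
            gen_zz_dataset(SynthSpec(1, 0.0, [0.0, 0.1, 0.2], TRUTH))


class TestRateSeriesGenerator:
    def test_arrhenius_is_exactly_linear(self):
        s = gen_rate_series(SynthSpec(1, 0.0, DEFAULT_TEMPERATURES, {"k0": 5.0, "Ea": 10.0}),
                            "arrhenius")
        x, y = 1.0 / s.temperatures, np.log(s.k)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        assert np.max(np.abs(resid)) < 1e-12
        assert -slope * R_KCAL == pytest.approx(10.0, rel=1e-10)

    def test_dimer_coupled_monomer_fraction_in_unit_interval(self):
        law = DimerCoupledRateLaw(k0=5.0, Ea_intrinsic=9.0, Kd0=100e-6,
                                  dH_assoc=30.0, Ctot=1e-3)
        s = gen_rate_series(SynthSpec(1, 0.0, DEFAULT_TEMPERATURES, law), "dimer_coupled")
        k_int = arrhenius_rate(s.temperatures, law.k0, law.Ea_intrinsic)
        f_M = s.k / k_int
        assert np.all(f_M > 0) and np.all(f_M <= 1)

    def test_zero_association_enthalpy_reduces_to_scaled_arrhenius(self):
        law = DimerCoupledRateLaw(k0=5.0, Ea_intrinsic=9.0, Kd0=100e-6,
                                  dH_assoc=0.0, Ctot=1e-3)
        k = dimer_coupled_rate(DEFAULT_TEMPERATURES, law)
        k_arr = arrhenius_rate(np.asarray(DEFAULT_TEMPERATURES), law.k0, law.Ea_intrinsic)
        f = monomer_fraction(law.Ctot, law.Kd0)
        np.testing.assert_allclose(k, f * k_arr, rtol=1e-12)

    def test_unknown_law_rejected(self):
        with pytest.raises(InvalidModelError):
            gen_rate_series(SynthSpec(1, 0.0, DEFAULT_TEMPERATURES, {}), "eyring")


class TestTitrationGenerator:
    def test_half_fraction_at_ctot_equal_kd(self):
        t = gen_titration(SynthSpec(1, 0.0, [50e-6, 116e-6, 500e-6], 116e-6))
        f = t.V_monomer[1] / (t.V_monomer[1] + t.V_dimer[1])
        assert f == pytest.approx(0.5, rel=1e-12)

    def test_dilution_limit(self):
        t = gen_titration(SynthSpec(1, 0.0, [116e-12, 1e-6], 116e-6))
        f = t.V_monomer[0] / (t.V_monomer[0] + t.V_dimer[0])
        assert f > 0.999

    def test_seed_determinism(self):
        a = gen_titration(SynthSpec(3, 0.05, [1e-5, 1e-4, 1e-3], 1e-4))
        b = gen_titration(SynthSpec(3, 0.05, [1e-5, 1e-4, 1e-3], 1e-4))
        assert np.array_equal(a.V_monomer, b.V_monomer)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidModelError):
            gen_titration(SynthSpec(1, 0.0, [0.0, 1e-4], 1e-4))


class TestDenaturationGenerator:
    def test_chemical_midpoint_is_half(self):
        grid = np.linspace(0.0, 5.0, 12)
        curve = gen_denaturation(SynthSpec(1, 0.0, grid, {"Cm": 2.66, "m": 1.6}), "chemical")
        from confex.stability import chemical_two_state
        assert chemical_two_state(2.66, 2.66, 1.6, 0, 0, 1, 0) == pytest.approx(0.5)
        mid_interp = np.interp(0.5, curve.response, curve.denaturant)
        assert mid_interp == pytest.approx(2.66, abs=0.02)

    def test_thermal_monotone_between_flat_baselines(self):
        grid = np.arange(25.0, 99.0, 2.0)
        curve = gen_denaturation(SynthSpec(1, 0.0, grid, {"Tm": 70.0, "dH_vH": 60.0}), "thermal")
        assert np.all(np.diff(curve.ellipticity) > 0)

    def test_midpoint_outside_grid_rejected(self):
        with pytest.raises(InvalidModelError):
            gen_denaturation(SynthSpec(1, 0.0, np.linspace(0, 5, 12), {"Cm": 7.0, "m": 1.6}),
                             "chemical")

    def test_seed_determinism(self):
        grid = np.linspace(0.0, 5.0, 12)
        a = gen_denaturation(SynthSpec(9, 0.02, grid, {"Cm": 2.0, "m": 2.0}), "chemical")
        b = gen_denaturation(SynthSpec(9, 0.02, grid, {"Cm": 2.0, "m": 2.0}), "chemical")
        assert np.array_equal(a.response, b.response)


class TestRotamerGenerator:
    def test_frozen_chain_constant(self):
        Q = np.zeros((6, 6))
        sm = gen_rotamer_traj(SynthSpec(1, 0.0, np.arange(0.0, 100.0, 1.0), Q))
        assert sm.true_transition_count == 0
        assert len(np.unique(sm.true_states.combined)) == 1

    def test_dwell_time_law(self):
        """Mean dwell ≈ 1/(total exit rate) within 5% over ≥ 2000 dwells."""
        Q = single_dihedral_rate_matrix(0.05, 0.05)
        exit_rate = 2 * 0.05 + 0.05
        sm = gen_rotamer_traj(SynthSpec(2, 0.0, np.linspace(0.0, 25000.0, 100), Q))
        assert len(sm.dwell_times) >= 2000
        assert sm.dwell_times.mean() == pytest.approx(1.0 / exit_rate, rel=0.05)

    def test_angular_noise_calibration(self):
        """10° wrapped Gaussian noise: circular sd in [9°, 11°] over 1e5 frames."""
        Q = single_dihedral_rate_matrix(0.01, 0.01)
        sm = gen_rotamer_traj(SynthSpec(3, 0.0, np.arange(0.0, 1e5, 1.0), Q),
                              angular_noise_sd=10.0)
        from confex.mddihedral import CHI1_CENTERS, wrap_angle
        centers = np.array([CHI1_CENTERS[c] for c in sm.true_states.chi1_states])
        resid = wrap_angle(sm.series.chi1 - centers)
        assert 9.0 <= resid.std() <= 11.0

    def test_stationary_occupancy(self):
        """Long-run occupancy matches the CTMC stationary law within 3 SE."""
        # detailed balance with π ∝ w: q_ij = w_j for single-dihedral moves
        w = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 2.0])
        Q = np.zeros((6, 6))
        for i, (a1, a2) in enumerate(CTMC_STATES):
            for j, (b1, b2) in enumerate(CTMC_STATES):
                if i != j and ((a1 == b1) != (a2 == b2)):
                    Q[i, j] = 0.05 * w[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        pi = ctmc_stationary(Q)
        np.testing.assert_allclose(pi, w / w.sum(), rtol=1e-10)
        sm = gen_rotamer_traj(SynthSpec(4, 0.0, np.arange(0.0, 3e4, 1.0), Q))
        idx = {s: i for i, s in enumerate(CTMC_STATES)}
        occ = np.bincount(
            [idx[(c1, c2)] for c1, c2 in zip(sm.true_states.chi1_states, sm.true_states.chi2_states)],
            minlength=6) / len(sm.true_states)
        n_eff = max(len(sm.dwell_times), 1)
        se = np.sqrt(pi * (1 - pi) / n_eff)
        assert np.all(np.abs(occ - pi) < 3 * se + 1e-12)

    def test_invalid_rate_matrix_rejected(self):
        Q = np.ones((6, 6))  # rows do not sum to zero
        with pytest.raises(InvalidModelError):
            gen_rotamer_traj(SynthSpec(1, 0.0, np.arange(10.0), Q))


class TestBackboneEnsemble:
    def test_zero_fluctuation_identical_frames(self):
        traj = gen_backbone_ensemble(SynthSpec(1, 0.0, np.arange(5), np.zeros(4)))
        assert np.all(traj.coords == traj.coords[0])

    def test_seed_determinism(self):
        a = gen_backbone_ensemble(SynthSpec(2, 0.0, np.arange(5), np.full(4, 0.3)))
        b = gen_backbone_ensemble(SynthSpec(2, 0.0, np.arange(5), np.full(4, 0.3)))
        assert np.array_equal(a.coords, b.coords)

    def test_single_residue_rejected(self):
        with pytest.raises(InvalidModelError):
            gen_backbone_ensemble(SynthSpec(1, 0.0, np.arange(5), np.zeros(1)))
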