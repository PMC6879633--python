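"""Dihedral geometry, rotamer states, transition counting, concerted motion, RMSF."""

import numpy as np
import pytest

from confex.exceptions import InvalidModelError
from confex.mddihedral import (
    DihedralSeries,
    RotamerStateSeries,
    assign_rotamer_states,
    compute_dihedral,
    compute_rmsf,
    count_label_changes,
    count_transitions,
    detect_concerted,
    extract_dihedrals,
    wrap_angle,
)
from confex.synthetic import (
    SynthSpec,
    gen_backbone_ensemble,
    gen_rotamer_traj,
    single_dihedral_rate_matrix,
)


def brute_force_dihedral(p1, p2, p3, p4):
    """Independent oracle: signed angle between the projections of the outer
    bonds onto the plane perpendicular to the central bond."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    axis = (p3 - p2) / np.linalg.norm(p3 - p2)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    cosang = np.clip(np.dot(u, v), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    # right-handed sign about the central bond: positive when the far bond is
    # rotated clockwise viewed along the axis (IUPAC convention)
    if np.dot(np.cross(u, v), axis) >= 0:
        ang = -ang
    return float(wrap_angle(ang))


class TestComputeDihedral:
    def test_trans_is_minus_180(self):
        assert compute_dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == -180.0

    def test_cis_is_zero(self):
        assert compute_dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == 0.0

    def test_matches_brute_force_on_random_quadruples(self):
        rng = np.random.default_rng(11)
        n = 0
        while n < 100:
            pts = rng.normal(size=(4, 3)) * 2.0
            try:
                a = compute_dihedral(*pts)
            except InvalidModelError:
                continue
            b = brute_force_dihedral(*pts)
            # compare on the circle (±180 wrap)
            assert abs(wrap_angle(a - b)) < 1e-9
            n += 1

    def test_rigid_motion_invariance_and_mirror_flip(self):
        rng = np.random.default_rng(3)
        pts = np.array([[0.1, 1.2, 0.3], [0, 0, 0], [1.5, 0.2, -0.1], [2.0, -1.0, 0.8]])
        ref = compute_dihedral(*pts)
        A = rng.normal(size=(3, 3))
        Q, R = np.linalg.qr(A)
        Q = Q @ np.diag(np.sign(np.diag(R)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        t = rng.normal(size=3) * 10
        moved = pts @ Q.T + t
        assert compute_dihedral(*moved) == pytest.approx(ref, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert compute_dihedral(*mirrored) == pytest.approx(-ref, abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(InvalidModelError):
            compute_dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 1, 0])
        with pytest.raises(InvalidModelError):
            compute_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestRotamerAssignment:
    @pytest.mark.parametrize("chi1, expected", [
        (-60.0, "g-"), (60.0, "g+"), (180.0, "t"), (-180.0, "t"),
        (300.0, "g-"),  # wraps to −60
        (0.0, "g+"),    # half-open boundary convention
        (-120.0, "g-"), (120.0, "t"),
    ])
    def test_chi1_bins(self, chi1, expected):
        s = assign_rotamer_states(DihedralSeries("W43", [chi1], [90.0], [0.0]))
        assert s.chi1_states[0] == expected

    @pytest.mark.parametrize("chi2, expected", [
        (90.0, "+90"), (-90.0, "-90"), (0.0, "+90"), (180.0, "-90"), (179.9, "+90"),
    ])
    def test_chi2_bins(self, chi2, expected):
        s = assign_rotamer_states(DihedralSeries("W43", [60.0], [chi2], [0.0]))
        assert s.chi2_states[0] == expected

    def test_wrap_invariance(self):
        angles = np.linspace(-179.0, 179.0, 37)
        base = assign_rotamer_states(DihedralSeries("W43", angles, angles, np.arange(37.0)))
        shifted = assign_rotamer_states(
            DihedralSeries("W43", angles + 720.0, angles - 360.0, np.arange(37.0)))
        assert np.array_equal(base.chi1_states, shifted.chi1_states)
        assert np.array_equal(base.chi2_states, shifted.chi2_states)


class TestTransitionCounting:
    def test_constant_series_zero(self):
        s = RotamerStateSeries("W43", ["g+"] * 10, ["+90"] * 10)
        assert count_transitions(s).combined == 0

    def test_alternating_states(self):
        labels = ["g+", "t"] * 5 + ["g+"]
        s = RotamerStateSeries("W43", labels, ["+90"] * 11)
        assert count_transitions(s, min_dwell=1).combined == 10

    def test_dwell_filter_removes_blips(self):
        labels = ["g+"] * 10 + ["t"] + ["g+"] * 10  # 1-frame excursion
        assert count_label_changes(labels, min_dwell=1) == 2
        assert count_label_changes(labels, min_dwell=2) == 0

    def test_monotone_in_min_dwell(self):
        Q = single_dihedral_rate_matrix(0.05, 0.05)
        sm = gen_rotamer_traj(SynthSpec(5, 0.0, np.arange(0.0, 1500.0, 1.0), Q),
                              angular_noise_sd=30.0)
        states = assign_rotamer_states(sm.series)
        counts = [count_transitions(states, md).combined for md in (1, 2, 3, 5, 8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_exact_match_against_jump_log_oracle(self):
        """Low angular noise: counted transitions equal the CTMC's own jumps."""
        Q = single_dihedral_rate_matrix(0.02, 0.02)
        for seed in range(3):
            sm = gen_rotamer_traj(SynthSpec(seed, 0.0, np.arange(0.0, 2000.0, 1.0), Q),
                                  angular_noise_sd=10.0)
            counted = count_transitions(assign_rotamer_states(sm.series)).combined
            # brute-force pairwise label-difference count on the true labels
            truth = sm.true_states.combined
            brute = int(np.count_nonzero(truth[1:] != truth[:-1]))
            assert counted == brute == sm.true_transition_count

    def test_high_noise_needs_dwell_filter(self):
        """40° angular noise: raw counting overcounts badly, a 5-frame dwell
        filter recovers the true count within 15% (median over seeds)."""
        Q = single_dihedral_rate_matrix(0.005, 0.005)
        rel_md5, overcount = [], []
        for seed in range(5):
            sm = gen_rotamer_traj(SynthSpec(seed, 0.0, np.arange(0.0, 8000.0, 1.0), Q),
                                  angular_noise_sd=40.0)
            states = assign_rotamer_states(sm.series)
            true = sm.true_transition_count
            overcount.append(count_transitions(states, 1).combined / true)
            rel_md5.append(abs(count_transitions(states, 5).combined - true) / true)
        assert min(overcount) > 2.0
        assert np.median(rel_md5) < 0.15


class TestDetectConcerted:
    def test_maximal_synchrony(self):
        labels_a = np.array((["g+"] * 20 + ["t"] * 20) * 5)
        s_a = RotamerStateSeries("a", labels_a, np.array(["+90"] * len(labels_a)))
        s_b = RotamerStateSeries("b", labels_a.copy(), np.array(["+90"] * len(labels_a)))
        r = detect_concerted(s_a, s_b, window=0, n_permutations=199, seed=0)
        assert r.p_value <= 1.0 / 200.0

    def test_constant_partner_gives_p_one(self):
        labels_a = np.array((["g+"] * 10 + ["t"] * 10) * 3)
        s_a = RotamerStateSeries("a", labels_a, np.array(["+90"] * 60))
        s_b = RotamerStateSeries("b", np.array(["g+"] * 60), np.array(["+90"] * 60))
        r = detect_concerted(s_a, s_b, window=2, n_permutations=99, seed=0)
        assert r.co_transition_count == 0
        assert r.p_value == 1.0

    def test_length_mismatch_rejected(self):
        s_a = RotamerStateSeries("a", ["g+"] * 5, ["+90"] * 5)
        s_b = RotamerStateSeries("b", ["g+"] * 6, ["+90"] * 6)
        with pytest.raises(InvalidModelError):
            detect_concerted(s_a, s_b)


class TestRMSF:
    def test_identical_frames_zero(self):
        traj = gen_backbone_ensemble(SynthSpec(1, 0.0, np.arange(10), np.zeros(5)))
        assert compute_rmsf(traj, burn_in_fraction=0.0).rmsf.max() < 1e-12

    def test_rigid_body_invariance(self):
        traj = gen_backbone_ensemble(SynthSpec(2, 0.0, np.arange(40), np.zeros(8)),
                                     rigid_body=True)
        assert compute_rmsf(traj, burn_in_fraction=0.0).rmsf.max() < 1e-6

    def test_reference_frame_independence(self):
        traj = gen_backbone_ensemble(SynthSpec(3, 0.0, np.arange(60), np.full(10, 0.4)))
        plain = compute_rmsf(traj, burn_in_fraction=0.0).rmsf
        spun = gen_backbone_ensemble(SynthSpec(3, 0.0, np.arange(60), np.full(10, 0.4)),
                                     rigid_body=True)
        # same seed: identical internal displacements, different global poses
        rigid = compute_rmsf(spun, burn_in_fraction=0.0).rmsf
        np.testing.assert_allclose(plain, rigid, atol=1e-6)

    def test_isotropic_limit(self):
        """Isotropic sd 0.5 Å per axis → per-residue RMSF ≈ 0.5·√3."""
        traj = gen_backbone_ensemble(SynthSpec(4, 0.0, np.arange(3000), np.full(50, 0.5)))
        prof = compute_rmsf(traj, burn_in_fraction=1.0 / 3.0)
        assert prof.rmsf.mean() == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_empty_selection_rejected(self):
        traj = gen_backbone_ensemble(SynthSpec(1, 0.0, np.arange(10), np.zeros(5)))
        with pytest.raises(InvalidModelError):
            compute_rmsf(traj, selection=("XX",))


class TestExtractDihedrals:
    def test_chi1_from_constructed_tryptophan(self):
        # N, CA, CB, CG placed so the N–CA–CB–CG dihedral is exactly −60°
        from confex.mddihedral import Trajectory

        def frame(chi1_deg):
            n = np.array([0.0, 1.45, 0.0])
            ca = np.zeros(3)
            cb = np.array([1.53, 0.0, 0.0])
            # rotating CG clockwise about the CA→CB axis (viewed from CA)
            # gives a positive dihedral, hence the sign flip
            rad = np.radians(-chi1_deg)
            cg = cb + np.array([0.3, 1.4 * np.cos(rad), 1.4 * np.sin(rad)])
            cd1 = cg + np.array([0.5, 1.2, 0.1])
            return np.stack([n, ca, cb, cg, cd1])

        coords = np.stack([frame(-60.0), frame(-60.0)])
        traj = Trajectory(
            coords=coords,
            atom_names=["N", "CA", "CB", "CG", "CD1"],
            residue_indices=np.array([43] * 5),
            residue_names=["TRP"] * 5,
        )
        series = extract_dihedrals(traj, 43)
        states = assign_rotamer_states(series)
        assert np.all(states.chi1_states == "g-")
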