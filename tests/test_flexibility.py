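"""Kabsch superposition, RMSF recovery and the ΔRMSF verdict."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import coronastat as cs
from coronastat.flexibility import (DeltaRMSFSummary, FlexibilityProfile,
                                    delta_rmsf, kabsch_superpose, rmsf)


def _rot(theta_deg, axis="z"):
    return Rotation.from_euler(axis, theta_deg, degrees=True).as_matrix()


class TestKabsch:
    def test_identical_sets_zero_rmsd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        y = x @ _rot(37).T + np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_independent_kabsch(self):
        """scipy's align_vectors is an independent least-squares path."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 3))
        y = x + rng.normal(scale=0.3, size=(8, 3))
        _, _, rmsd = kabsch_superpose(x, y)
        xc, yc = x - x.mean(0), y - y.mean(0)
        rot_sp, rssd = Rotation.align_vectors(xc, yc)
        ref = np.sqrt(rssd**2 / len(x))
        assert rmsd == pytest.approx(ref, abs=1e-9)

    def test_no_random_rotation_beats_optimum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 3))
        y = x + rng.normal(scale=0.2, size=(6, 3))
        _, _, best = kabsch_superpose(x, y)
        xc, yc = x - x.mean(0), y - y.mean(0)
        for rot in Rotation.random(2000, random_state=4):
            trial = np.sqrt(((yc @ rot.as_matrix().T - xc) ** 2)
                            .sum(axis=1).mean())
            assert trial >= best - 1e-9

    def test_collinear_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line[::-1])


class TestRMSF:
    def test_static_trajectory_is_zero(self, toy_protein):
        traj = cs.Trajectory(toy_protein,
                             [toy_protein.coords.copy() for _ in range(3)])
        prof = rmsf(traj)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_sigma_recovery_closed_form(self, toy_protein):
        """Isotropic jitter with per-coordinate σ gives RMSF = σ√3."""
        sigma = 0.02
        traj = cs.make_jitter_trajectory(toy_protein, sigma, 2000, seed=9)
        prof = rmsf(traj)
        assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_two_block_profile_ratio(self, toy_protein):
        n_res = len(toy_protein.residues())
        profile = np.where(np.arange(n_res) < n_res // 2, 0.01, 0.05)
        traj = cs.make_jitter_trajectory(toy_protein, profile, 1500, seed=10)
        prof = rmsf(traj)
        lo = prof.rmsf[: n_res // 2].mean()
        hi = prof.rmsf[n_res // 2:].mean()
        assert hi / lo == pytest.approx(5.0, rel=0.10)

    def test_invariant_under_global_rigid_motion(self, toy_protein):
        traj = cs.make_jitter_trajectory(toy_protein, 0.02, 60, seed=11)
        base = rmsf(traj).rmsf
        rot = _rot(63, "y")
        moved = cs.Trajectory(
            toy_protein,
            [f @ rot.T + np.array([3.0, 1.0, -2.0]) for f in traj.frames],
        )
        np.testing.assert_allclose(rmsf(moved).rmsf, base, atol=1e-9)

    def test_sigma_estimate_unbiased_over_seeds(self, toy_protein):
        estimates = []
        for seed in range(5):
            traj = cs.make_jitter_trajectory(toy_protein, 0.03, 400, seed=seed)
            estimates.append(rmsf(traj).rmsf.mean() / np.sqrt(3))
        assert np.mean(estimates) == pytest.approx(0.03, rel=0.03)

    def test_needs_at_least_two_frames(self, toy_protein):
        traj = cs.Trajectory(toy_protein, [toy_protein.coords])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj)


def _profile(values, start_seq=130):
    values = np.asarray(values, float)
    return FlexibilityProfile(values,
                              np.arange(start_seq, start_seq + len(values)))


class TestDeltaRMSF:
    def test_identical_profiles_indeterminate(self):
        p = _profile(np.full(25, 0.03))
        s = delta_rmsf(p, p, active_site=(136, 150))
        assert np.all(s.delta == 0.0)
        assert s.verdict == "indeterminate"

    def test_rigidified_span_is_compromised(self, toy_protein):
        free = cs.make_jitter_trajectory(toy_protein, 0.03, 300, seed=1)
        ads = cs.make_jitter_trajectory(toy_protein, 0.01, 300, seed=2)
        s = delta_rmsf(rmsf(ads), rmsf(free), active_site=(10, 40))
        assert s.n_negative > 0.9 * (s.n_negative + s.n_positive)
        assert s.verdict == "compromised"

    def test_balanced_span_is_preserved(self):
        base = np.full(25, 0.03)
        delta = np.zeros(25)
        delta[5:12] = 0.005   # 7 residues more mobile
        delta[12:20] = -0.005  # 8 residues rigidified
        s = delta_rmsf(_profile(base + delta), _profile(base),
                       active_site=(135, 154))
        assert (s.n_positive, s.n_negative) == (7, 8)
        assert s.verdict == "preserved"

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(5)
        a = _profile(0.02 + rng.uniform(0, 0.02, 30))
        b = _profile(0.02 + rng.uniform(0, 0.02, 30))
        s1 = delta_rmsf(a, b, active_site=(136, 150))
        s2 = delta_rmsf(b, a, active_site=(136, 150))
        np.testing.assert_allclose(s1.delta, -s2.delta)
        assert (s1.n_positive, s1.n_negative) == (s2.n_negative, s2.n_positive)

    def test_span_outside_numbering_rejected(self):
        p = _profile(np.full(10, 0.02), start_seq=1)
        with pytest.raises(ValueError, match="active site"):
            delta_rmsf(p, p, active_site=(136, 150))
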