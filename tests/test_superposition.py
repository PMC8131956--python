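"""Kabsch superposition, RMSD/RMSF/Rg metrics and replicate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from stressmap.errors import DegenerateInputError, ShapeError
from stressmap.structure_io import Trajectory
from stressmap.superposition import (RmsdSeries, aggregate_replicates,
                                     atom_masses, domain_rmsd_series,
                                     kabsch_superpose, mean_sem,
                                     radius_of_gyration, windowed_rmsf)


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    trans = rng.normal(0, 10, 3)
    return rot, trans


def _grid_search_rmsd(mobile, reference, coarse_deg=10, fine_deg=1):
    """Independent oracle: best RMSD over a rotation grid (refined to 1 deg).

    Translation is removed by centering; the rotation is scanned on a full
    coarse Euler grid then refined locally at 1-degree resolution.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_for(rots):
        rotated = np.einsum("rij,nj->rni", rots, mob)
        return np.sqrt(np.mean(np.sum((rotated - ref) ** 2, axis=2), axis=1))

    coarse = np.array(np.meshgrid(
        np.arange(0, 360, coarse_deg),
        np.arange(-90, 90.1, coarse_deg),
        np.arange(0, 360, coarse_deg))).reshape(3, -1).T
    mats = Rotation.from_euler("zyx", coarse, degrees=True).as_matrix()
    best = coarse[np.argmin(rmsd_for(mats))]

    offsets = np.arange(-coarse_deg, coarse_deg + 0.1, fine_deg)
    fine = np.array(np.meshgrid(*[best[k] + offsets for k in range(3)]))
    fine = fine.reshape(3, -1).T
    mats = Rotation.from_euler("zyx", fine, degrees=True).as_matrix()
    return float(rmsd_for(mats).min())


class TestKabsch:
    def test_identity_gives_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        pts = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 1.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        reference = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 2]])
        mobile = reference + rng.normal(0, 0.3, reference.shape)
        rot, trans = _random_rigid(rng)
        mobile = mobile @ rot.T + trans
        _, _, rmsd = kabsch_superpose(mobile, reference)
        oracle = _grid_search_rmsd(mobile, reference)
        assert rmsd == pytest.approx(oracle, abs=0.01)
        assert rmsd <= oracle + 1e-9   # analytic optimum can only be better

    def test_shape_and_size_errors(self):
        with pytest.raises(ShapeError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_fitted_rmsd_never_exceeds_unfitted(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(8, 3))
        b = r.normal(size=(8, 3))
        _, _, fitted = kabsch_superpose(a, b)
        unfitted = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert fitted <= unfitted + 1e-9


class TestDomainRmsd:
    def test_static_trajectory_is_zero(self, toy_fab, domain_map):
        frames = np.repeat(toy_fab.coords[None], 4, axis=0)
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        ser = domain_rmsd_series(traj, toy_fab, "CL", domain_map)
        np.testing.assert_allclose(ser.values, 0.0, atol=1e-9)

    def test_rigid_rotation_of_region_is_removed(self, toy_fab, domain_map, rng):
        rot, trans = _random_rigid(rng)
        frames = np.stack([toy_fab.coords, toy_fab.coords @ rot.T + trans])
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        ser = domain_rmsd_series(traj, toy_fab, "VL", domain_map)
        np.testing.assert_allclose(ser.values, 0.0, atol=1e-8)

    def test_designed_deformation_matches_closed_form(self, toy_fab, toy_spec,
                                                      domain_map):
        from stressmap.synthetic import StressProfile, simulate_stress_trajectory
        profile = StressProfile("low_ph_like", jitter_sigma=0.0,
                                deformation_amplitude=2.0)
        trajs, gt = simulate_stress_trajectory(toy_fab, profile, n_frames=11,
                                               n_replicates=1, spec=toy_spec)
        ser = domain_rmsd_series(trajs[0], toy_fab, "CL", domain_map)
        expected = np.linspace(0, 1, 11) * gt["deformation"]["final_rmsd"]
        np.testing.assert_allclose(ser.values, expected, atol=1e-6)


class TestWindowedRmsf:
    def test_window_count_for_100ns(self, toy_fab, domain_map):
        frames = np.repeat(toy_fab.coords[None], 101, axis=0)
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        profiles = windowed_rmsf(traj, "VL", domain_map, window_ns=10.0)
        assert len(profiles) == 10

    def test_static_trajectory_has_zero_rmsf(self, toy_fab, domain_map):
        frames = np.repeat(toy_fab.coords[None], 10, axis=0)
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        for prof in windowed_rmsf(traj, "CL", domain_map, window_ns=10.0):
            np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_alternating_single_atom_recovers_delta(self, toy_fab, domain_map):
        delta = 0.4
        frames = np.repeat(toy_fab.coords[None], 10, axis=0)
        atom = 0                                     # N of residue 1 (VL)
        frames[::2, atom, 0] += delta
        frames[1::2, atom, 0] -= delta
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        prof = windowed_rmsf(traj, "VL", domain_map, window_ns=10.0)[0]
        res1 = prof.values[prof.residues == 1][0]
        n_atoms_res1 = int(np.sum(toy_fab.resseq == 1))
        # residue value is the mean over its atoms; only one atom moves
        assert res1 == pytest.approx(delta / n_atoms_res1, rel=0.05)

    def test_rmsf_invariant_to_rigid_motion_per_window(self, toy_fab,
                                                       domain_map, rng):
        frames = np.repeat(toy_fab.coords[None], 6, axis=0)
        frames += rng.normal(0, 0.1, frames.shape)
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        base = windowed_rmsf(traj, "VH", domain_map, window_ns=10.0)[0]
        rot, trans = _random_rigid(rng)
        moved = Trajectory(toy_fab, frames @ rot.T + trans,
                           frame_interval_ns=1.0)
        shifted = windowed_rmsf(moved, "VH", domain_map, window_ns=10.0)[0]
        np.testing.assert_allclose(base.values, shifted.values, atol=1e-8)

    def test_too_short_window_rejected(self, toy_fab, domain_map):
        frames = np.repeat(toy_fab.coords[None], 4, axis=0)
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        with pytest.raises(DegenerateInputError):
            windowed_rmsf(traj, "VL", domain_map, window_ns=1.0)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.ones(1)) == 0.0

    def test_two_equal_masses_4A_apart(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(2.0)

    def test_unequal_masses_match_direct_sum(self, rng):
        coords = rng.normal(size=(5, 3))
        masses = rng.uniform(1, 30, 5)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        direct = np.sqrt(sum(m * np.sum((x - com) ** 2)
                             for m, x in zip(masses, coords)) / masses.sum())
        assert radius_of_gyration(coords, masses) == pytest.approx(direct)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_rigid_motion(self, seed):
        r = np.random.default_rng(seed)
        coords = r.normal(size=(6, 3))
        masses = r.uniform(1, 16, 6)
        rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        moved = coords @ rot.T + r.normal(0, 5, 3)
        assert radius_of_gyration(moved, masses) == pytest.approx(
            radius_of_gyration(coords, masses), rel=1e-9)

    def test_zero_mass_rejected(self):
        with pytest.raises(DegenerateInputError):
            radius_of_gyration(np.zeros((2, 3)), np.zeros(2))


class TestReplicateStats:
    def test_identical_series_have_zero_sem(self):
        t = np.arange(5.0)
        series = [RmsdSeries("CL", t, np.ones(5), r) for r in range(6)]
        agg = aggregate_replicates(series)
        np.testing.assert_allclose(agg.sem, 0.0)
        assert agg.n_replicates == 6

    def test_two_replicate_sem_is_one(self):
        t = np.zeros(1)
        series = [RmsdSeries("CL", t, np.array([1.0]), 0),
                  RmsdSeries("CL", t, np.array([3.0]), 1)]
        agg = aggregate_replicates(series)
        assert agg.mean[0] == pytest.approx(2.0)
        assert agg.sem[0] == pytest.approx(1.0)   # sd=sqrt(2), /sqrt(2)

    def test_single_replicate_flagged(self):
        with pytest.warns(UserWarning, match="single replicate"):
            agg = aggregate_replicates(
                [RmsdSeries("CL", np.arange(3.0), np.arange(3.0), 0)])
        assert agg.single_replicate
        np.testing.assert_allclose(agg.sem, 0.0)

    def test_mismatched_time_axes_rejected(self):
        with pytest.raises(ShapeError):
            aggregate_replicates([
                RmsdSeries("CL", np.arange(3.0), np.zeros(3), 0),
                RmsdSeries("CL", np.arange(3.0) + 1, np.zeros(3), 1)])

    def test_mean_sem_against_formula(self, rng):
        x = rng.normal(size=(4, 7))
        m, e = mean_sem(x)
        np.testing.assert_allclose(m, x.mean(0))
        np.testing.assert_allclose(e, x.std(0, ddof=1) / 2.0)


def test_unknown_element_gets_carbon_mass():
    with pytest.warns(UserWarning, match="carbon"):
        masses = atom_masses(["C", "N", "Xx"])
    assert masses[2] == masses[0]
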