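"""Superposition and stability metrics against hand and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindscape import (
    AtomRecord,
    Selection,
    Topology,
    Trajectory,
    average_replicas,
    com_distance_series,
    kabsch_fit,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    select_stable_replica,
)
from bindscape.errors import (
    DegenerateGeometryError,
    DimensionError,
    EmptyInputError,
    ValidationError,
)
from bindscape.geometry import SeriesResult


def _top(n, masses=None):
    masses = masses if masses is not None else [12.0] * n
    return Topology(atoms=[
        AtomRecord(index=i, name=f"A{i}", residue_id=i + 1, residue_name="R",
                   segment="protein", mass=masses[i])
        for i in range(n)
    ])


def _all(n):
    return Selection(indices=tuple(range(n)))


def grid_min_rmsd(mobile, reference, coarse=36, top_k=5, refine=3):
    """Brute-force rigid-fit RMSD: exhaustive Euler-angle grid, then local
    refinement around the best few candidates (all vectorized)."""
    from scipy.spatial.transform import Rotation

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def rmsd_batch(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()
        moved = np.einsum("mij,aj->mai", R, mob_c)
        return np.sqrt(np.mean(np.sum((moved - ref_c[None]) ** 2, axis=2),
                               axis=1))

    step = 2 * np.pi / coarse
    aa, bb, gg = np.meshgrid(np.arange(coarse) * step,
                             np.linspace(0, np.pi, coarse // 2),
                             np.arange(coarse) * step, indexing="ij")
    angles = np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])
    r = rmsd_batch(angles)
    order = np.argsort(r)[:top_k]
    best = float(r[order[0]])
    for idx in order:
        a, b, g = angles[idx]
        local_step = step
        for _ in range(refine):
            grid = [np.linspace(v - local_step, v + local_step, 9)
                    for v in (a, b, g)]
            la, lb, lg = np.meshgrid(*grid, indexing="ij")
            cand = np.column_stack([la.ravel(), lb.ravel(), lg.ravel()])
            rr = rmsd_batch(cand)
            k = int(np.argmin(rr))
            a, b, g = cand[k]
            best = min(best, float(rr[k]))
            local_step = 2 * local_step / 8
    return best


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        rot, trans, rmsd = kabsch_fit(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_motion_recovered(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(6, 3))
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.normal(size=3) * 5
        mobile = ref @ R.T + t
        rot, trans, rmsd = kabsch_fit(mobile, ref)
        assert rmsd <= 1e-8
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(mobile @ rot.T + trans, ref, atol=1e-8)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_rotation_grid_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(4, 3)) * 2
        mobile = ref + rng.normal(size=(4, 3)) * 0.3
        _, _, rmsd = kabsch_fit(mobile, ref)
        assert rmsd == pytest.approx(grid_min_rmsd(mobile, ref), abs=1e-3)

    def test_weighted_fit_matches_weighted_brute_force(self):
        # weights change the optimum; verify against a direct computation
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(5, 3))
        mobile = ref + rng.normal(size=(5, 3)) * 0.2
        w = rng.uniform(0.5, 3.0, size=5)
        rot, trans, rmsd = kabsch_fit(mobile, ref, weights=w)
        moved = mobile @ rot.T + trans
        direct = np.sqrt(np.sum(w * np.sum((moved - ref) ** 2, axis=1)) / w.sum())
        assert rmsd == pytest.approx(direct, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(line, line)


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        top = _top(4)
        frame = np.random.default_rng(0).normal(size=(4, 3))
        traj = Trajectory(np.repeat(frame[None], 3, axis=0), 1.0)
        out = rmsd_series(traj, top, _all(4), fit_selection=_all(4))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_rotated_copies_zero_after_fit(self):
        top = _top(5)
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(5, 3))
        frames = [ref]
        for s in range(2, 5):
            R = Rotation.random(random_state=s).as_matrix()
            frames.append(ref @ R.T + rng.normal(size=3))
        traj = Trajectory(np.stack(frames), 1.0)
        out = rmsd_series(traj, top, _all(5), fit_selection=_all(5))
        assert np.all(out.values <= 1e-8)

    def test_hand_computed_two_atom_case(self):
        # no superposition: deviations are read straight off the coordinates
        top = _top(2)
        frames = np.array([
            [[0.0, 0, 0], [1, 0, 0]],
            [[1.0, 0, 0], [2, 0, 0]],   # both atoms shifted 1 -> rmsd 1
            [[0.0, 0, 0], [1, 1, 0]],   # atom 1 off by 1 -> sqrt(1/2)
        ])
        traj = Trajectory(frames, 1.0)
        out = rmsd_series(traj, top, _all(2), fit_selection=None)
        np.testing.assert_allclose(
            out.values, [0.0, 1.0, np.sqrt(0.5)], atol=1e-12)

    def test_empty_selection_rejected(self):
        top = _top(3)
        traj = Trajectory(np.zeros((2, 3, 3)), 1.0)
        with pytest.raises(EmptyInputError):
            rmsd_series(traj, top, Selection(indices=()))


class TestAverageReplicas:
    def test_identity_and_hand_case(self):
        s1 = SeriesResult(np.array([1.0, 1.0]), 1.0)
        s3 = SeriesResult(np.array([3.0, 3.0]), 1.0)
        out = average_replicas(s1, s3)
        np.testing.assert_allclose(out.values, [2.0, 2.0])
        same = average_replicas(s1, s1, s1)
        np.testing.assert_allclose(same.values, s1.values)

    def test_matches_direct_mean(self):
        rng = np.random.default_rng(2)
        arrs = [rng.normal(size=7) ** 2 for _ in range(3)]
        out = average_replicas(*[SeriesResult(a, 2.0) for a in arrs])
        np.testing.assert_allclose(out.values, np.mean(arrs, axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            average_replicas(SeriesResult(np.zeros(3), 1.0),
                             SeriesResult(np.zeros(4), 1.0))


class TestRmsf:
    def test_static_trajectory_zero(self):
        top = _top(4)
        frame = np.random.default_rng(0).normal(size=(4, 3)) * 3
        traj = Trajectory(np.repeat(frame[None], 5, axis=0), 1.0)
        out = rmsf(traj, top, _all(4))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_oscillating_atom_has_rmsf_d(self):
        # atom 3 oscillates +/- d along x; the fit is anchored on the
        # static triangle so there is no net fit motion
        d = 0.4
        base = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [5, 5, 1]])
        frames = []
        for k in range(6):
            f = base.copy()
            f[3, 0] += d if k % 2 == 0 else -d
            frames.append(f)
        top = _top(4)
        traj = Trajectory(np.stack(frames), 1.0)
        out = rmsf(traj, top, _all(4), fit_selection=Selection(indices=(0, 1, 2)))
        assert out.values[3] == pytest.approx(d, abs=1e-9)
        np.testing.assert_allclose(out.values[:3], 0.0, atol=1e-9)

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(4)
        top = _top(5)
        frames = rng.normal(size=(6, 5, 3))
        traj = Trajectory(frames, 1.0)
        ref_out = rmsf(traj, top, _all(5))
        R = Rotation.random(random_state=8).as_matrix()
        moved = frames @ R.T + np.array([3.0, -2.0, 1.0])
        out2 = rmsf(Trajectory(moved, 1.0), top, _all(5))
        np.testing.assert_allclose(out2.values, ref_out.values, atol=1e-8)

    def test_single_frame_rejected(self):
        top = _top(4)
        with pytest.raises(ValidationError):
            rmsf(Trajectory(np.zeros((1, 4, 3)), 1.0), top, _all(4))


class TestRadiusOfGyration:
    def test_two_equal_masses_two_angstrom_apart(self):
        top = _top(2)
        traj = Trajectory(np.array([[[0.0, 0, 0], [2, 0, 0]]]), 1.0)
        out = radius_of_gyration(traj, top, _all(2))
        assert out.values[0] == pytest.approx(1.0)

    def test_coincident_atoms_zero(self):
        top = _top(3)
        traj = Trajectory(np.ones((2, 3, 3)), 1.0)
        out = radius_of_gyration(traj, top, _all(3))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        masses = rng.uniform(1, 20, 5)
        top = _top(5, masses=list(masses))
        coords = rng.normal(size=(3, 5, 3)) * 4
        traj = Trajectory(coords, 1.0)
        out = radius_of_gyration(traj, top, _all(5))
        for f in range(3):
            com = (masses[:, None] * coords[f]).sum(0) / masses.sum()
            direct = np.sqrt((masses * ((coords[f] - com) ** 2).sum(1)).sum()
                             / masses.sum())
            assert out.values[f] == pytest.approx(direct, abs=1e-12)


class TestComDistance:
    def test_identical_selections_zero(self):
        top = _top(3)
        traj = Trajectory(np.random.default_rng(0).normal(size=(4, 3, 3)), 1.0)
        out = com_distance_series(traj, top, _all(3), _all(3))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_three_four_five(self):
        top = _top(2, masses=[1.0, 1.0])
        traj = Trajectory(np.array([[[0.0, 0, 0], [3, 4, 0]]]), 1.0)
        out = com_distance_series(traj, top, Selection(indices=(0,)),
                                  Selection(indices=(1,)))
        assert out.values[0] == pytest.approx(5.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        masses = rng.uniform(1, 10, 6)
        top = _top(6, masses=list(masses))
        coords = rng.normal(size=(2, 6, 3)) * 3
        a, b = Selection(indices=(0, 1, 2)), Selection(indices=(3, 4, 5))
        out = com_distance_series(Trajectory(coords, 1.0), top, a, b)
        for f in range(2):
            ca = (masses[:3, None] * coords[f, :3]).sum(0) / masses[:3].sum()
            cb = (masses[3:, None] * coords[f, 3:]).sum(0) / masses[3:].sum()
            assert out.values[f] == pytest.approx(np.linalg.norm(ca - cb))


class TestSelectStableReplica:
    def test_minimum_variance_wins(self):
        rng = np.random.default_rng(7)
        series = []
        for scale in (0.5, 0.1, 0.3):
            series.append(SeriesResult(1.0 + scale * rng.normal(size=200), 1.0))
        assert select_stable_replica(series, window_frames=100) == 1

    def test_single_replica(self):
        s = SeriesResult(np.arange(10.0), 1.0)
        assert select_stable_replica([s], window_frames=5) == 0

    def test_tie_goes_to_lower_index(self):
        s = SeriesResult(np.ones(10), 1.0)
        assert select_stable_replica([s, s, s], window_frames=5) == 0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            select_stable_replica([], window_frames=5)
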