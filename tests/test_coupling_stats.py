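"""RMSD/RMSF/DCCM statistics against closed forms and a literal oracle."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kvcoupling import (
    DCCMatrix,
    SegmentDefinition,
    TrajectoryError,
    analysis_window,
    average_dccm,
    dccm,
    delta_dccm,
    rmsd_series,
    rmsf_profile,
    segment_pair_submatrix,
)
from kvcoupling.coupling_stats import ZeroVarianceWarning

from conftest import make_trajectory


def dccm_oracle(coords):
    """Literal double-loop implementation of the correlation formula."""
    n_frames, n_atoms = coords.shape[:2]
    mean = coords.mean(axis=0)
    disp = coords - mean
    out = np.empty((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(n_atoms):
            num = sum(float(np.dot(disp[t, i], disp[t, j])) for t in range(n_frames))
            vi = sum(float(np.dot(disp[t, i], disp[t, i])) for t in range(n_frames))
            vj = sum(float(np.dot(disp[t, j], disp[t, j])) for t in range(n_frames))
            out[i, j] = num / np.sqrt(vi * vj)
    return out


class TestRmsd:
    def test_static_trajectory_is_zero(self):
        base = np.random.default_rng(0).normal(size=(5, 3))
        traj = make_trajectory(np.stack([base] * 4))
        series = rmsd_series(traj, superpose=False)
        assert np.allclose(series.values, 0.0)

    def test_uniform_shift_without_superposition(self):
        base = np.random.default_rng(1).normal(size=(6, 3))
        traj = make_trajectory(np.stack([base, base + [1.0, 0, 0]]))
        series = rmsd_series(traj, superpose=False)
        assert series.values[0] == pytest.approx(0.0)
        assert series.values[1] == pytest.approx(1.0)

    def test_rigid_rotation_removed_by_superposition(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 3)) * 5
        rot = Rotation.random(rng=rng).as_matrix()
        traj = make_trajectory(np.stack([base, base @ rot.T + [3, -1, 2]]))
        series = rmsd_series(traj, superpose=True, atom_names=None)
        assert series.values[1] < 1e-8

    def test_frame_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(6, 5, 3))
        coords[0] = coords[0] * 0 + rng.normal(size=(5, 3))  # arbitrary reference
        traj = make_trajectory(coords)
        series = rmsd_series(traj, superpose=False)
        perm = np.array([0, 3, 1, 5, 2, 4])  # keep reference frame first
        permuted = make_trajectory(coords[perm])
        series_p = rmsd_series(permuted, superpose=False)
        assert np.allclose(series_p.values, series.values[perm])


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        base = np.random.default_rng(0).normal(size=(4, 3))
        traj = make_trajectory(np.stack([base] * 3))
        prof = rmsf_profile(traj, superpose=False)
        assert np.allclose(prof.values, 0.0)

    def test_single_frame_rejected(self):
        traj = make_trajectory(np.random.default_rng(0).normal(size=(1, 4, 3)))
        with pytest.raises(TrajectoryError, match="[Ff]luctuation"):
            rmsf_profile(traj)

    def test_isotropic_gaussian_closed_form(self):
        """Isotropic jitter with sigma per axis gives RMSF = sigma * sqrt(3)."""
        rng = np.random.default_rng(42)
        sigma = 0.5
        base = rng.normal(size=(20, 3)) * 10
        coords = base[None] + rng.normal(scale=sigma, size=(10_000, 20, 3))
        prof = rmsf_profile(make_trajectory(coords), superpose=False)
        assert np.allclose(prof.values, sigma * np.sqrt(3), rtol=0.02)

    def test_only_jittered_residue_fluctuates(self):
        rng = np.random.default_rng(5)
        coords = np.zeros((50, 2, 3))
        coords[:, 0] = [0, 0, 0]
        coords[:, 1] = [10, 0, 0] + rng.normal(scale=0.3, size=(50, 3))
        prof = rmsf_profile(make_trajectory(coords), superpose=False)
        assert prof.values[0] == pytest.approx(0.0)
        assert prof.values[1] > 0.1

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(30, 4, 3))
        prof = rmsf_profile(make_trajectory(coords), superpose=False)
        shuffled = rng.permutation(coords, axis=0)
        prof_s = rmsf_profile(make_trajectory(shuffled), superpose=False)
        assert np.allclose(prof.values, prof_s.values)


class TestDccm:
    def test_matches_double_loop_oracle(self):
        """Vectorized DCCM equals the literal formula on small instances."""
        rng = np.random.default_rng(10)
        for n_atoms, n_frames in [(2, 5), (3, 10), (5, 20)]:
            coords = rng.normal(size=(n_frames, n_atoms, 3))
            matrix = dccm(make_trajectory(coords), superpose=False)
            assert np.max(np.abs(matrix.values - dccm_oracle(coords))) < 1e-12

    def test_perfectly_correlated_and_anticorrelated(self):
        rng = np.random.default_rng(11)
        disp = rng.normal(size=(40, 1, 3))
        coords = np.concatenate(
            [disp, disp + 10.0, -disp + 20.0], axis=1
        )  # atom 1 copies atom 0; atom 2 mirrors it
        matrix = dccm(make_trajectory(coords), superpose=False)
        assert matrix.values[0, 1] == pytest.approx(1.0)
        assert matrix.values[0, 2] == pytest.approx(-1.0)

    def test_independent_displacements_decorrelate(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(10_000, 4, 3))
        matrix = dccm(make_trajectory(coords), superpose=False)
        off = matrix.values[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05  # sampling error ~ N^(-1/2)

    def test_invariants_on_random_inputs(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            coords = rng.normal(size=(rng.integers(5, 30), rng.integers(2, 8), 3))
            m = dccm(make_trajectory(coords), superpose=False)
            assert np.allclose(m.values, m.values.T, atol=1e-12)
            assert np.allclose(np.diag(m.values), 1.0)
            assert np.all(np.abs(m.values) <= 1.0 + 1e-12)

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(14)
        coords = rng.normal(size=(25, 3, 3))
        m1 = dccm(make_trajectory(coords), superpose=False)
        m2 = dccm(make_trajectory(rng.permutation(coords, axis=0)), superpose=False)
        assert np.allclose(m1.values, m2.values)

    def test_zero_variance_residue_flagged_not_zeroed(self):
        rng = np.random.default_rng(15)
        coords = rng.normal(size=(30, 3, 3))
        coords[:, 1] = [5.0, 5.0, 5.0]  # motionless residue
        with pytest.warns(ZeroVarianceWarning, match="A:2"):
            m = dccm(make_trajectory(coords), superpose=False)
        assert np.all(np.isnan(m.values[1, :]))
        assert np.all(np.isnan(m.values[:, 1]))
        assert np.isfinite(m.values[0, 2])

    def test_multiple_atoms_per_residue_rejected(self):
        traj = make_trajectory(np.random.default_rng(0).normal(size=(5, 3, 3)))
        traj.atoms.loc[1, "residue_number"] = 1  # collide with residue 1
        traj.atoms.loc[1, "atom_name"] = "CB"
        with pytest.raises(TrajectoryError, match="one representative atom"):
            dccm(traj, atom_names=None, superpose=False)


class TestAverageAndDelta:
    def _matrix(self, values, ids=None):
        n = values.shape[0]
        ids = ids or [("A", i + 1) for i in range(n)]
        return DCCMatrix(residue_ids=ids, values=values, n_frames=10)

    def test_average_of_one_is_itself(self):
        rng = np.random.default_rng(20)
        raw = rng.uniform(-0.5, 0.5, (4, 4))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        m = self._matrix(values)
        assert np.allclose(average_dccm([m]).values, values)

    def test_average_of_m_and_minus_m(self):
        rng = np.random.default_rng(21)
        raw = rng.uniform(-0.5, 0.5, (3, 3))
        off = (raw + raw.T) / 2
        np.fill_diagonal(off, 1.0)
        neg = -off.copy()
        np.fill_diagonal(neg, 1.0)
        avg = average_dccm([self._matrix(off), self._matrix(neg)])
        assert np.allclose(np.diag(avg.values), 1.0)
        assert np.allclose(avg.values[~np.eye(3, dtype=bool)], 0.0)

    def test_replicate_mean_reduces_estimator_error(self, ref_geometry, seg_pair):
        """The 5-replicate mean beats single replicates on average (Monte Carlo)."""
        from conftest import block_config
        from kvcoupling import generate_correlated_trajectory

        seg_a, seg_b = seg_pair
        rho = 0.8
        singles, mean_err = [], None
        mats = []
        for seed in range(5):
            traj = generate_correlated_trajectory(
                ref_geometry, block_config(seg_a, seg_b, rho, n_frames=400, seed=seed)
            )
            m = dccm(traj, superpose=False)
            mats.append(m)
            singles.append(abs(segment_pair_submatrix(m, seg_a, seg_b).mean - rho))
        pooled = segment_pair_submatrix(average_dccm(mats), seg_a, seg_b)
        assert abs(pooled.mean - rho) < np.mean(singles)

    def test_delta_identical_inputs_zero(self):
        rng = np.random.default_rng(22)
        raw = rng.uniform(-0.5, 0.5, (4, 4))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        d = delta_dccm(self._matrix(values), self._matrix(values.copy()))
        assert np.allclose(d.values, 0.0)

    def test_delta_antisymmetric(self):
        rng = np.random.default_rng(23)
        mats = []
        for _ in range(2):
            raw = rng.uniform(-0.5, 0.5, (3, 3))
            v = (raw + raw.T) / 2
            np.fill_diagonal(v, 1.0)
            mats.append(self._matrix(v))
        d_ab = delta_dccm(mats[0], mats[1])
        d_ba = delta_dccm(mats[1], mats[0])
        assert np.allclose(d_ab.values, -d_ba.values)

    def test_ordering_mismatch_rejected(self):
        m1 = self._matrix(np.eye(2), ids=[("A", 1), ("A", 2)])
        m2 = self._matrix(np.eye(2), ids=[("A", 2), ("A", 1)])
        with pytest.raises(ValueError, match="ordering"):
            average_dccm([m1, m2])
        with pytest.raises(ValueError, match="ordering"):
            delta_dccm(m1, m2)


class TestSegmentPairSubmatrix:
    def _matrix(self, n=120, chain="A", start=235):
        ids = [(chain, start + i) for i in range(n)]
        rng = np.random.default_rng(30)
        raw = rng.uniform(-0.4, 0.4, (n, n))
        v = (raw + raw.T) / 2
        np.fill_diagonal(v, 1.0)
        return DCCMatrix(residue_ids=ids, values=v, n_frames=10)

    def test_full_set_returns_whole_matrix(self):
        m = self._matrix(n=10)
        seg = SegmentDefinition("all", "A", 235, 244)
        sub = segment_pair_submatrix(m, seg, seg)
        assert sub.values.shape == (10, 10)
        assert np.allclose(sub.values, m.values)

    def test_block_shape_from_ranges(self):
        m = self._matrix(n=120)
        s4 = SegmentDefinition("S4", "A", 235, 241)
        filt = SegmentDefinition("filter", "A", 310, 320)
        sub = segment_pair_submatrix(m, s4, filt)
        assert sub.values.shape == (7, 11)
        assert sub.mean == pytest.approx(np.mean(sub.values))

    def test_single_residue_block(self):
        m = self._matrix(n=10)
        sa = SegmentDefinition("a", "A", 236, 236)
        sb = SegmentDefinition("b", "A", 240, 240)
        sub = segment_pair_submatrix(m, sa, sb)
        assert sub.values.shape == (1, 1)
        assert sub.values[0, 0] == m.values[1, 5]

    def test_uncontained_segment_rejected(self):
        m = self._matrix(n=10)
        with pytest.raises(ValueError, match="not in matrix"):
            segment_pair_submatrix(m, SegmentDefinition("x", "B", 1, 3),
                                   SegmentDefinition("y", "A", 235, 236))


class TestAnalysisWindow:
    def _traj(self, n_frames=120, dt=0.25):
        coords = np.random.default_rng(0).normal(size=(n_frames, 3, 3))
        return make_trajectory(coords, dt=dt)

    def test_production_window_frame_count(self):
        """[10, 30] ns of a 120-frame 0.25 ns run keeps 81 snapshots."""
        win = analysis_window(self._traj(), 10.0, 30.0)
        assert win.n_frames == 81
        assert win.timestamps[0] == pytest.approx(10.0)
        assert win.timestamps[-1] == pytest.approx(30.0)

    def test_unbounded_window_is_identity(self):
        traj = self._traj()
        win = analysis_window(traj, 0.0, np.inf)
        assert win.n_frames == traj.n_frames

    def test_tail_window_selects_final_frame(self):
        win = analysis_window(self._traj(), 29.9, 30.0)
        assert win.n_frames == 1
        assert win.timestamps[0] == pytest.approx(30.0)

    def test_empty_and_inverted_windows_rejected(self):
        traj = self._traj()
        with pytest.raises(TrajectoryError):
            analysis_window(traj, 40.0, 50.0)
        with pytest.raises(TrajectoryError):
            analysis_window(traj, 20.0, 10.0)
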