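"""Superposition, fluctuation series, and covariance PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import holdscan as hs
import holdscan.pca as pca
from holdscan.traj import Trajectory
from conftest import make_topology


def _random_coords(rng, n):
    return rng.normal(scale=5.0, size=(n, 3))


def _make_traj(coords_per_frame):
    coords = np.asarray(coords_per_frame, dtype=float)
    return Trajectory(make_topology(coords.shape[1]), coords)


class TestKabsch:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        x = _random_coords(rng, 10)
        R, t, rmsd = pca.kabsch_superpose(x, x)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        x = _random_coords(rng, 12)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ Rz.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = pca.kabsch_superpose(x, y)
        np.testing.assert_allclose(R, Rz, atol=1e-6)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(pca.apply_transform(x, R, t), y, atol=1e-8)

    def test_noise_rmsd_matches_noise_model(self):
        # Fitting removes 6 rigid dof, so for isotropic noise of width sigma
        # on N atoms E[rmsd^2] ~= sigma^2 (3N - 6) / N.
        rng = np.random.default_rng(2)
        n, sigma, reps = 20, 0.1, 1000
        x = _random_coords(rng, n)
        sq = np.empty(reps)
        for r in range(reps):
            y = x + rng.normal(scale=sigma, size=x.shape)
            _, _, rmsd = pca.kabsch_superpose(y, x)
            sq[r] = rmsd**2
        expected = sigma**2 * (3 * n - 6) / n
        assert sq.mean() == pytest.approx(expected, rel=0.05)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            pca.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            pca.kabsch_superpose(line, line)


class TestRMSDSeries:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(3)
        base = _random_coords(rng, 8)
        traj = _make_traj([base] * 5)
        np.testing.assert_allclose(pca.rmsd_series(traj, np.arange(8)), 0.0, atol=1e-10)

    def test_rigid_translation_removed(self):
        rng = np.random.default_rng(4)
        base = _random_coords(rng, 8)
        traj = _make_traj([base, base + np.array([5.0, 0, 0])])
        assert pca.rmsd_series(traj, np.arange(8))[1] == pytest.approx(0.0, abs=1e-8)

    def test_two_state_step_change(self):
        rng = np.random.default_rng(5)
        base = _random_coords(rng, 8)
        shifted = base.copy()
        shifted[:4] += np.array([0, 0, 3.0])  # internal change, not rigid
        traj = _make_traj([base] * 5 + [shifted] * 5)
        series = pca.rmsd_series(traj, np.arange(8))
        assert np.all(series[:5] < 1e-8)
        assert np.all(series[5:] > 1.0)


class TestRMSF:
    def test_rigid_trajectory_is_zero(self):
        rng = np.random.default_rng(6)
        base = _random_coords(rng, 10)
        frames = []
        for ang in np.linspace(0, 60, 8):
            R = Rotation.from_euler("y", ang, degrees=True).as_matrix()
            frames.append(base @ R.T + ang * 0.1)
        np.testing.assert_allclose(
            pca.rmsf(_make_traj(frames), np.arange(10)), 0.0, atol=1e-6
        )

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(7)
        base = _random_coords(rng, 30)
        sigma = 0.5
        frames = [base.copy() for _ in range(400)]
        for f in frames:
            f[0] += rng.normal(scale=sigma, size=3)
        out = pca.rmsf(_make_traj(frames), np.arange(30))
        assert out[0] == pytest.approx(sigma * np.sqrt(3), rel=0.1)
        assert np.all(out[1:] < 0.2)

    def test_ordering_follows_planted_sigmas(self):
        rng = np.random.default_rng(8)
        base = _random_coords(rng, 12)
        sigmas = np.where(np.arange(12) < 6, 0.1, 0.8)  # core vs loop
        frames = [
            base + rng.normal(size=base.shape) * sigmas[:, None] for _ in range(200)
        ]
        out = pca.rmsf(_make_traj(frames), np.arange(12))
        assert out[6:].min() > out[:6].max()

    def test_single_frame_rejected(self):
        traj = _make_traj([np.random.default_rng(0).normal(size=(5, 3))])
        with pytest.raises(ValueError):
            pca.rmsf(traj, np.arange(5))


def _rigid_modes(base):
    """Orthonormal basis of the 6 rigid-body modes at a reference geometry."""
    n = base.shape[0]
    centered = base - base.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        modes.append(np.cross(axis, centered).ravel())
    q, _ = np.linalg.qr(np.column_stack(modes))
    return q.T


def _planted_two_mode_traj(rng, n_atoms=10, n_frames=400, vars=(4.0, 1.0)):
    """Frames displaced along two planted internal modes with known variances.

    The raw single-atom axes are projected out of the rigid-body subspace so
    that superposition cannot absorb them; returns (trajectory, mode_u,
    mode_v) with the purified orthonormal mode vectors in 3N space.
    """
    base = _random_coords(rng, n_atoms)
    rigid = _rigid_modes(base)
    u = np.zeros(3 * n_atoms)
    u[0] = 1.0        # atom 0, x
    v = np.zeros(3 * n_atoms)
    v[4] = 1.0        # atom 1, y
    u -= rigid.T @ (rigid @ u)
    u /= np.linalg.norm(u)
    v -= rigid.T @ (rigid @ v) + (v @ u) * u
    v /= np.linalg.norm(v)
    amps_u = rng.normal(scale=np.sqrt(vars[0]), size=n_frames)
    amps_v = rng.normal(scale=np.sqrt(vars[1]), size=n_frames)
    frames = [
        base + (a * u + b * v).reshape(n_atoms, 3)
        for a, b in zip(amps_u, amps_v)
    ]
    return _make_traj(frames), u, v


class TestFitPCA:
    def test_planted_axis_recovered(self):
        rng = np.random.default_rng(9)
        traj, u, v = _planted_two_mode_traj(rng)
        model = pca.fit_pca(traj, np.arange(10))
        # superposition slightly mixes the mode into rigid dof; the leading
        # eigenvector must still align with the planted axis
        assert abs(model.eigenvectors[0] @ u) > 0.99
        ratio = model.eigenvalues[0] / model.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_isotropic_noise_gives_flat_spectrum(self):
        rng = np.random.default_rng(10)
        base = _random_coords(rng, 8)
        frames = [base + rng.normal(scale=0.3, size=base.shape) for _ in range(2000)]
        model = pca.fit_pca(_make_traj(frames), np.arange(8))
        nonzero = model.eigenvalues[model.eigenvalues > 1e-6]
        assert nonzero.max() / nonzero.min() < 2.0

    def test_brute_force_covariance_oracle(self):
        # explicit double loop over frames on a 5-atom, 20-frame fixture
        rng = np.random.default_rng(11)
        base = _random_coords(rng, 5)
        frames = [base + rng.normal(scale=0.5, size=base.shape) for _ in range(20)]
        traj = _make_traj(frames)
        fitted, _ = pca.superposed_coords(traj, np.arange(5))
        X = fitted.reshape(20, 15)
        mu = X.mean(axis=0)
        C_oracle = np.zeros((15, 15))
        for f in range(20):
            d = X[f] - mu
            for i in range(15):
                for j in range(15):
                    C_oracle[i, j] += d[i] * d[j]
        C_oracle /= 20
        model = pca.fit_pca(traj, np.arange(5))
        C_impl = model.eigenvectors.T @ np.diag(model.eigenvalues) @ model.eigenvectors
        np.testing.assert_allclose(C_impl, C_oracle, atol=1e-10)
        assert model.eigenvalues.sum() == pytest.approx(np.trace(C_oracle), rel=1e-8)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        traj, _, _ = _planted_two_mode_traj(rng, n_frames=100)
        model = pca.fit_pca(traj, np.arange(10))
        moved = traj.coords.copy()
        for f in range(traj.n_frames):
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            moved[f] = moved[f] @ R.T + rng.normal(scale=10.0, size=3)
        model2 = pca.fit_pca(_make_traj(moved), np.arange(10))
        top = model.eigenvalues[:2]
        np.testing.assert_allclose(model2.eigenvalues[:2], top, rtol=1e-6)

    def test_orthonormality_and_trace(self):
        rng = np.random.default_rng(13)
        traj, _, _ = _planted_two_mode_traj(rng, n_frames=50)
        model = pca.fit_pca(traj, np.arange(10))
        gram = model.eigenvectors @ model.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(model.eigenvalues)), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-10)
        assert np.all(model.eigenvalues >= 0)


class TestProjection:
    def test_mean_structure_projects_to_zero(self):
        rng = np.random.default_rng(14)
        traj, _, _ = _planted_two_mode_traj(rng, n_frames=60)
        model = pca.fit_pca(traj, np.arange(10))
        mean_traj = _make_traj([model.mean_coords])
        proj = pca.project(mean_traj, model, k=2, sel=np.arange(10))
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)

    def test_projection_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(15)
        traj, _, _ = _planted_two_mode_traj(rng, n_frames=300)
        model = pca.fit_pca(traj, np.arange(10))
        proj = pca.project(traj, model, k=2, sel=np.arange(10))
        for j in range(2):  # the two planted (nonzero) modes
            assert proj[:, j].var() == pytest.approx(model.eigenvalues[j], rel=1e-4)

    def test_variance_explained(self):
        rng = np.random.default_rng(16)
        traj, _, _ = _planted_two_mode_traj(rng, n_frames=2000, vars=(4.0, 1.0))
        model = pca.fit_pca(traj, np.arange(10))
        assert pca.variance_explained(model, len(model.eigenvalues)) == pytest.approx(1.0)
        assert pca.variance_explained(model, 0) == 0.0
        assert pca.variance_explained(model, 1) == pytest.approx(0.8, abs=0.05)


class TestSubspaceOverlap:
    def test_self_overlap_is_identity_diagonal(self):
        rng = np.random.default_rng(17)
        traj, _, _ = _planted_two_mode_traj(rng)
        model = pca.fit_pca(traj, np.arange(10))
        M, summary = pca.subspace_overlap(model, model, k=5)
        np.testing.assert_allclose(np.diag(M), 1.0, atol=1e-10)
        assert summary == pytest.approx(1.0)

    def test_replicate_runs_share_leading_modes(self):
        # two noise realizations of the same planted 2-mode system overlap
        # strongly on PC-1 (the reported band is >= 50%)
        models = []
        for seed in (18, 19):
            rng = np.random.default_rng(seed)
            traj, _, _ = _planted_two_mode_traj(rng, n_frames=300)
            models.append(pca.fit_pca(traj, np.arange(10)))
        M, _ = pca.subspace_overlap(models[0], models[1], k=2)
        assert M[0, 0] >= 0.5

    def test_orthogonal_planted_modes_do_not_overlap(self):
        rng = np.random.default_rng(20)
        traj, u, v = _planted_two_mode_traj(rng, n_frames=500)
        model = pca.fit_pca(traj, np.arange(10))
        assert abs(model.eigenvectors[0] @ model.eigenvectors[1]) < 1e-10
        M, _ = pca.subspace_overlap(model, model, k=2)
        assert M[0, 1] == pytest.approx(0.0, abs=1e-8)
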