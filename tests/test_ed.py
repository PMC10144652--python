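"""Essential dynamics: fitting, PCA, free-energy landscape, rotamers, basins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mdpmm import units
from mdpmm.ed import (ROTAMER_BOUNDARIES, classify_rotamer,
                      covariance_eigendecomposition, dihedral_series,
                      fit_trajectory, free_energy_landscape,
                      locate_basins_and_extract)
from mdpmm.electronic import ValidationError
from mdpmm.fixtures import (SOFT_DIHEDRAL, FixtureSpec, _chain_geometry,
                            mock_conformational_trajectory)

KB = units.KB_KJ_MOL_K


def _reference(seed=0, n_atoms=6):
    rng = np.random.default_rng(seed)
    return rng.normal(scale=0.2, size=(n_atoms, 3))


class TestFitTrajectory:
    def test_pure_rigid_motion_recovered(self):
        ref = _reference()
        masses = np.arange(1.0, 7.0)
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(ref) + np.array([1.0, -2.0, 0.5])
        frames = np.stack([ref, moved])
        fitted = fit_trajectory(frames, masses, ref)
        np.testing.assert_allclose(fitted[1], ref, atol=1e-10)

    def test_identity_when_frame_equals_reference(self):
        ref = _reference(1)
        frames = np.stack([ref, ref])
        fitted = fit_trajectory(frames, np.ones(6), ref)
        np.testing.assert_allclose(fitted, frames, atol=1e-12)

    def test_internal_geometry_preserved(self):
        ref = _reference(2)
        rng = np.random.default_rng(3)
        frame = Rotation.random(rng=rng).apply(ref + rng.normal(
            scale=0.02, size=ref.shape)) + 5.0
        fitted = fit_trajectory(np.stack([ref, frame]), np.ones(6), ref)
        d_before = np.linalg.norm(frame[:, None] - frame[None], axis=-1)
        d_after = np.linalg.norm(fitted[1][:, None] - fitted[1][None], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-10)

    def test_optimal_vs_random_rigid_transforms(self):
        """Kabsch beats 1000 random rigid placements of the same frame."""
        rng = np.random.default_rng(4)
        ref = _reference(5)
        masses = rng.uniform(1, 16, size=6)
        distorted = ref + rng.normal(scale=0.03, size=ref.shape)
        frame = Rotation.random(rng=rng).apply(distorted) + rng.normal(size=3)

        def wrmsd(x):
            return np.sqrt(np.sum(masses[:, None] * (x - ref) ** 2)
                           / masses.sum())

        fitted = fit_trajectory(np.stack([ref, frame]), masses, ref)[1]
        best = wrmsd(fitted)
        w = masses / masses.sum()
        for _ in range(1000):
            trial = Rotation.random(rng=rng).apply(frame - w @ frame) \
                + w @ ref + rng.normal(scale=0.01, size=3)
            assert wrmsd(trial) >= best - 1e-12

    def test_fitting_idempotent(self):
        rng = np.random.default_rng(6)
        ref = _reference(7)
        frames = np.stack([Rotation.random(rng=rng).apply(
            ref + rng.normal(scale=0.02, size=ref.shape)) for _ in range(4)])
        masses = np.ones(6)
        once = fit_trajectory(frames, masses, ref)
        twice = fit_trajectory(once, masses, ref)
        assert np.abs(twice - once).max() < 1e-10

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            fit_trajectory(np.zeros((2, 5, 3)), np.ones(5), np.zeros((6, 3)))


class TestCovariance:
    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(8)
        n_atoms = 10
        direction = rng.normal(size=3 * n_atoms)
        direction /= np.linalg.norm(direction)
        amps = rng.normal(scale=0.05, size=400)
        base = rng.normal(scale=0.2, size=3 * n_atoms)
        X = base + amps[:, None] * direction \
            + rng.normal(scale=1e-4, size=(400, 3 * n_atoms))
        space = covariance_eigendecomposition(X.reshape(400, n_atoms, 3), 2)
        cosine = abs(space.eigenvectors[:, 0] @ direction)
        assert cosine > 0.999
        assert space.eigenvalues[1] < 1e-3 * space.eigenvalues[0]

    def test_trace_conservation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 8, 3))
        space = covariance_eigendecomposition(X, 2)
        flat = X.reshape(300, -1)
        total_var = ((flat - flat.mean(0)) ** 2).mean(0).sum()
        assert space.eigenvalues.sum() == pytest.approx(total_var, rel=1e-8)

    def test_isotropic_spectrum_flat(self):
        rng = np.random.default_rng(10)
        X = rng.normal(scale=0.1, size=(20000, 4, 3))
        space = covariance_eigendecomposition(X, 2)
        ev = space.eigenvalues
        assert ev[0] / ev[-1] < 1.2  # flat within sampling error

    def test_two_soft_torsions_dominate(self):
        """Chain with one soft torsion: leading eigenvalues dominate the
        fluctuation, as for sugar hydroxymethyl rotation."""
        frames, _, masses, _ = mock_conformational_trajectory(
            FixtureSpec(n_frames=800, seed=21))
        fitted = fit_trajectory(frames, masses, frames[0])
        space = covariance_eigendecomposition(fitted, 2)
        top2 = space.eigenvalues[:2].sum()
        assert top2 / space.eigenvalues.sum() > 0.8

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(11)
        space = covariance_eigendecomposition(
            rng.normal(size=(50, 5, 3)), 3)
        V = space.eigenvectors
        assert np.abs(V.T @ V - np.eye(15)).max() < 1e-10

    def test_n_select_out_of_range(self):
        with pytest.raises(ValidationError):
            covariance_eigendecomposition(np.zeros((5, 2, 3)), 7)


class TestFreeEnergy:
    def test_equal_counts_zero_difference(self):
        proj = np.array([[0.1, 0.1]] * 100 + [[0.9, 0.9]] * 100)
        grid = free_energy_landscape(proj, bins=2, temperature=300.0)
        sampled_vals = grid.free_energy[grid.sampled]
        np.testing.assert_allclose(sampled_vals, 0.0, atol=1e-12)

    def test_boltzmann_closed_form(self):
        # counts ratio e^-1 at 300 K: dA = kB * 300 = 2.494 kJ/mol
        n1 = 100000
        n2 = int(round(n1 * np.exp(-1)))
        proj = np.array([[0.0, 0.0]] * n1 + [[1.0, 1.0]] * n2)
        grid = free_energy_landscape(proj, bins=2, temperature=300.0)
        vals = np.sort(grid.free_energy[grid.sampled])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(KB * 300.0, rel=1e-4)
        assert vals[1] == pytest.approx(2.494, abs=2e-3)

    def test_two_basin_recovery_within_tolerance(self):
        """dA_true = 3 kJ/mol at 300 K recovered within 0.15 kJ/mol."""
        dA_true = 3.0
        rng = np.random.default_rng(13)
        n = 100000
        p2 = np.exp(-dA_true / (KB * 300.0))
        w = np.array([1.0, p2]) / (1.0 + p2)
        which = rng.choice(2, size=n, p=w)
        centers = np.array([[0.0, 0.0], [1.0, 0.0]])
        proj = centers[which] + rng.normal(scale=0.08, size=(n, 2))
        grid = free_energy_landscape(proj, bins=60, temperature=300.0)
        rcs = locate_basins_and_extract(grid, np.zeros((n, 1, 3)), proj,
                                        n_rc=2)
        assert len({rc.basin_id for rc in rcs}) == 2
        probs = sorted((rc.probability for rc in rcs), reverse=True)
        dA_est = -KB * 300.0 * np.log(probs[1] / probs[0])
        assert dA_est == pytest.approx(dA_true, abs=0.15)

    def test_count_scaling_leaves_dA_unchanged(self):
        rng = np.random.default_rng(14)
        proj = rng.normal(size=(500, 2))
        g1 = free_energy_landscape(proj, bins=10)
        g2 = free_energy_landscape(np.repeat(proj, 3, axis=0), bins=10)
        np.testing.assert_allclose(g2.free_energy[g1.sampled],
                                   g1.free_energy[g1.sampled], atol=1e-10)

    def test_minimum_is_exactly_zero_and_unsampled_is_nan(self):
        rng = np.random.default_rng(15)
        proj = rng.normal(size=(200, 2))
        grid = free_energy_landscape(proj, bins=30)
        assert np.nanmin(grid.free_energy) == 0.0
        assert np.all(np.isnan(grid.free_energy[~grid.sampled]))
        assert grid.counts.sum() == 200

    def test_empty_projections_rejected(self):
        with pytest.raises(ValidationError):
            free_energy_landscape(np.zeros((0, 2)))


class TestDihedral:
    def test_cis_and_trans(self):
        cis = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0],
                        [0.0, -1.0, 0.0], [1.0, -1.0, 0.0]])
        assert dihedral_series(cis, (0, 1, 2, 3))[0] == pytest.approx(0.0)
        trans = cis.copy()
        trans[3] = [-1.0, -1.0, 0.0]
        assert dihedral_series(trans, (0, 1, 2, 3))[0] == pytest.approx(180.0)

    def test_matches_mdanalysis_oracle(self):
        from MDAnalysis.lib.distances import calc_dihedrals
        rng = np.random.default_rng(16)
        frames = rng.normal(scale=0.3, size=(50, 4, 3))
        ours = dihedral_series(frames, (0, 1, 2, 3))
        # MDAnalysis returns radians in (-pi, pi]
        theirs = np.array([
            calc_dihedrals(f[0][None].astype(np.float32) * 10,
                           f[1][None].astype(np.float32) * 10,
                           f[2][None].astype(np.float32) * 10,
                           f[3][None].astype(np.float32) * 10)[0]
            for f in frames])
        theirs_deg = np.rad2deg(theirs) % 360.0
        diff = np.abs(ours - theirs_deg)
        diff = np.minimum(diff, 360.0 - diff)
        assert diff.max() < 1e-3  # float32 oracle precision

    def test_chain_generator_round_trip_high_precision(self):
        """Placement torsion equals measured dihedral to < 1e-9 degrees."""
        for t in (0.0, 17.3, 60.0, 181.5, 240.0, 359.0):
            tors = np.full(7, 120.0)
            tors[SOFT_DIHEDRAL[3] - 3] = t
            x = _chain_geometry(tors)
            assert dihedral_series(x, SOFT_DIHEDRAL)[0] == pytest.approx(
                t, abs=1e-9)

    def test_collinear_rejected(self):
        frames = np.array([[[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]])
        with pytest.raises(ValidationError, match="collinear"):
            dihedral_series(frames, (0, 1, 2, 3))


class TestRotamer:
    @pytest.mark.parametrize("angle,expected", [
        (180.0, "GT"), (60.0, "GG"), (240.0, "GG"), (0.0, "TG"),
        (359.0, "TG"),
    ])
    def test_class_centers(self, angle, expected):
        assert classify_rotamer(angle) == expected

    @pytest.mark.parametrize("boundary,below,above", [
        (30.0, "TG", "GG"), (120.0, "GG", "GT"),
        (210.0, "GT", "GG"), (300.0, "GG", "TG"),
    ])
    def test_circular_boundaries(self, boundary, below, above):
        assert classify_rotamer(boundary - 1.0) == below
        assert classify_rotamer(boundary + 1.0) == above

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-720.0, max_value=720.0,
                     allow_nan=False))
    def test_total_and_nearest_center(self, angle):
        cls = classify_rotamer(angle)
        assert cls in ("GT", "GG", "TG")
        centers = {"TG": [0.0, 360.0], "GG": [60.0, 240.0], "GT": [180.0]}
        d = angle % 360.0

        def circ_dist(a, b):
            return min(abs(a - b), 360.0 - abs(a - b))

        best = min(centers, key=lambda c: min(circ_dist(d, x)
                                              for x in centers[c]))
        # at exact midpoints either neighbor is acceptable
        if all(abs(circ_dist(d, b)) > 1e-9 for b in ROTAMER_BOUNDARIES):
            assert cls == best


class TestBasinExtraction:
    def test_single_basin_single_rc_at_mode(self):
        rng = np.random.default_rng(17)
        proj = rng.normal(scale=0.1, size=(20000, 2))
        grid = free_energy_landscape(proj, bins=40)
        frames = rng.normal(size=(20000, 3, 3))
        rcs = locate_basins_and_extract(grid, frames, proj, n_rc=1)
        assert len(rcs) == 1
        assert rcs[0].probability == pytest.approx(1.0)
        assert np.linalg.norm(rcs[0].essential_coords) < 0.05

    def test_two_equal_basins_half_half(self):
        rng = np.random.default_rng(18)
        n = 40000
        which = rng.choice(2, size=n)
        centers = np.array([[-1.0, 0.0], [1.0, 0.0]])
        proj = centers[which] + rng.normal(scale=0.1, size=(n, 2))
        grid = free_energy_landscape(proj, bins=50)
        rcs = locate_basins_and_extract(grid, np.zeros((n, 1, 3)), proj,
                                        n_rc=2)
        assert len(rcs) == 2
        for rc in rcs:
            assert rc.probability == pytest.approx(0.5, abs=0.02)

    def test_rc_count_below_basin_count_rejected(self):
        rng = np.random.default_rng(19)
        n = 20000
        which = rng.choice(2, size=n)
        centers = np.array([[-1.0, 0.0], [1.0, 0.0]])
        proj = centers[which] + rng.normal(scale=0.1, size=(n, 2))
        grid = free_energy_landscape(proj, bins=50)
        with pytest.raises(ValidationError, match="basin"):
            locate_basins_and_extract(grid, np.zeros((n, 1, 3)), proj, n_rc=1)

    def test_probabilities_sum_to_one_and_scale(self):
        """Eleven RCs over distinct basins: per-RC probabilities land on the
        0.04-0.15 scale of a several-conformer sugar table."""
        rng = np.random.default_rng(20)
        n = 60000
        w = np.array([0.5, 0.3, 0.2])
        which = rng.choice(3, size=n, p=w)
        centers = np.array([[-1.5, 0.0], [0.0, 1.2], [1.5, -0.5]])
        proj = centers[which] + rng.normal(scale=0.12, size=(n, 2))
        grid = free_energy_landscape(proj, bins=60)
        rcs = locate_basins_and_extract(grid, np.zeros((n, 1, 3)), proj,
                                        n_rc=11)
        assert len(rcs) == 11
        assert sum(rc.probability for rc in rcs) == pytest.approx(1.0)
        assert len({rc.basin_id for rc in rcs}) == 3
        for rc in rcs:
            assert 0.01 < rc.probability < 0.3
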