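"""RMSD/RMSF/Rg/block-averaging correctness against closed forms and oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ffentropy import (
    DegenerateGeometryError,
    InsufficientDataError,
    ParameterError,
    TimeSeries,
    TrajectoryEnsemble,
    block_average,
    distribution_estimate,
    kabsch_superpose,
    radius_of_gyration_series,
    rmsd_series,
    rmsf_per_residue,
)
from ffentropy.model import StructureModel
from ffentropy.synth import build_ideal_helix, gaussian_ensemble, rigid_body_ensemble

from .oracles import direct_rg, quaternion_grid_min_rmsd


def _point_model(xyz, masses=None):
    n = len(xyz)
    return StructureModel(
        atom_names=["CA"] * n,
        residue_ids=np.arange(n),
        residue_names=["GLY"] * n,
        coordinates=np.asarray(xyz, float),
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
    )


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)

    def test_rigid_motion_recovered(self):
        pts = np.random.default_rng(1).normal(size=(5, 3)) * 3
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot90.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-8

    def test_rotation_is_always_proper(self):
        # mirrored target would favor a reflection; det must stay +1
        pts = np.random.default_rng(2).normal(size=(8, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_quaternion_grid_oracle(self, weighted):
        rng = np.random.default_rng(3)
        for i in range(10):
            ref = rng.normal(size=(5, 3)) * 3
            mob = ref + rng.normal(size=(5, 3)) * 0.5
            mob = mob @ Rotation.random(random_state=rng).as_matrix().T
            w = rng.uniform(0.5, 2.0, 5) if weighted else None
            _, _, r_kabsch = kabsch_superpose(mob, ref, w)
            r_grid = quaternion_grid_min_rmsd(mob, ref, w, seed=100 + i)
            assert abs(r_kabsch - r_grid) < 1e-6

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_degenerate(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_rigid_body_ensemble_is_zero(self, helix10):
        ens = rigid_body_ensemble(helix10, 20, seed=4)
        series = rmsd_series(ens, helix10)
        assert np.all(series.values < 1e-6)

    def test_single_displaced_atom_bounded(self, helix10):
        coords = np.repeat(helix10.coordinates[None], 3, axis=0)
        d = 2.0
        ca = helix10.select("ca")
        coords[1, ca[4], 0] += d
        series = rmsd_series(TrajectoryEnsemble(coords, helix10), helix10)
        assert series.values[0] < 1e-10
        assert series.values[2] < 1e-10
        assert 0 < series.values[1] <= d

    def test_global_rigid_motion_invariance(self, helix10):
        ens = gaussian_ensemble(helix10, 0.3, 10, seed=5)
        base = rmsd_series(ens, helix10).values
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True)
        moved = ens.coordinates @ rot.as_matrix().T + np.array([3.0, -2.0, 1.0])
        again = rmsd_series(
            TrajectoryEnsemble(moved, helix10), helix10
        ).values
        np.testing.assert_allclose(again, base, atol=1e-8)


class TestRmsf:
    def test_rigid_ensemble_zero(self, helix10):
        ens = rigid_body_ensemble(helix10, 15, seed=6)
        profile = rmsf_per_residue(ens, "ca", align=True)
        assert np.all(profile.rmsf < 1e-6)

    def test_gaussian_closed_form(self, helix10):
        sigma = 0.4
        ens = gaussian_ensemble(helix10, sigma, 8000, seed=7)
        profile = rmsf_per_residue(ens, "ca", align=False)
        expected = sigma * np.sqrt(3.0)
        np.testing.assert_allclose(profile.rmsf, expected, rtol=0.05)

    def test_doubled_sigma_doubles_rmsf(self, helix10):
        sigma = np.full(helix10.n_residues, 0.3)
        sigma[5] = 0.6
        ens = gaussian_ensemble(helix10, sigma, 8000, seed=8)
        profile = rmsf_per_residue(ens, "ca", align=False)
        others = np.delete(profile.rmsf, 5).mean()
        assert profile.rmsf[5] / others == pytest.approx(2.0, rel=0.05)

    def test_window_validation(self, helix10):
        ens = gaussian_ensemble(helix10, 0.2, 10, seed=9)
        with pytest.raises(ParameterError):
            rmsf_per_residue(ens, "ca", window=(5, 20))
        with pytest.raises(InsufficientDataError):
            rmsf_per_residue(ens, "ca", window=(3, 4))


class TestRadiusOfGyration:
    def test_two_points_closed_form(self):
        model = _point_model([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        ens = TrajectoryEnsemble(model.coordinates[None], model)
        rg = radius_of_gyration_series(ens, selection="all")
        assert rg.values[0] == pytest.approx(1.0)

    def test_single_point_zero(self):
        model = _point_model([[1.0, 2.0, 3.0]])
        ens = TrajectoryEnsemble(model.coordinates[None], model)
        assert radius_of_gyration_series(ens).values[0] == 0.0

    def test_cube_corners_direct_sum(self):
        corners = np.array(
            [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)],
            dtype=float,
        )
        model = _point_model(corners)
        ens = TrajectoryEnsemble(corners[None], model)
        rg = radius_of_gyration_series(ens, selection="all")
        assert rg.values[0] == pytest.approx(np.sqrt(3.0))
        assert rg.values[0] == pytest.approx(direct_rg(corners))

    def test_mass_weighting_against_direct_sum(self, helix10):
        ens = gaussian_ensemble(helix10, 0.2, 3, seed=10)
        rg = radius_of_gyration_series(ens, mass_weighted=True)
        expected = direct_rg(
            ens.coordinates[1][helix10.select("heavy")],
            helix10.masses[helix10.select("heavy")],
        )
        assert rg.values[1] == pytest.approx(expected)

    def test_rigid_ensemble_constant(self, helix10):
        ens = rigid_body_ensemble(helix10, 30, seed=11)
        rg = radius_of_gyration_series(ens)
        assert np.ptp(rg.values) < 1e-8


class TestBlockAverage:
    def test_constant_series(self):
        stats = block_average(np.full(100, 2.5), 10)
        assert stats.mean == pytest.approx(2.5)
        assert stats.standard_error == 0.0
        assert stats.n_blocks == 10

    @pytest.mark.parametrize("block_length", [5, 10, 25, 50])
    def test_mean_equals_grand_mean_when_dividing(self, block_length):
        values = np.random.default_rng(12).normal(size=100)
        stats = block_average(values, block_length)
        assert stats.mean == pytest.approx(values.mean())

    def test_partial_block_discarded(self):
        values = np.concatenate([np.zeros(20), np.full(7, 100.0)])
        stats = block_average(values, 10)
        assert stats.n_blocks == 2
        assert stats.mean == pytest.approx(0.0)

    def test_iid_gaussian_standard_error_scale(self):
        # 1000 replicate series: the block SE should estimate 1/sqrt(n)
        rng = np.random.default_rng(13)
        ses = [
            block_average(rng.normal(size=8000), 500).standard_error
            for _ in range(200)
        ]
        expected = 1.0 / np.sqrt(8000)
        assert np.mean(ses) == pytest.approx(expected, rel=0.1)

    def test_insufficient_blocks(self):
        with pytest.raises(InsufficientDataError):
            block_average(np.arange(15.0), 10)


class TestDistributionEstimate:
    def test_identical_values_single_bin(self):
        dens = distribution_estimate(np.full(50, 3.0), 0.5)
        assert dens.density.max() == pytest.approx(1.0 / 0.5)
        assert (dens.density > 0).sum() == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalization(self, seed):
        values = np.random.default_rng(seed).normal(10, 2, 500)
        dens = distribution_estimate(values, 0.3)
        assert dens.density.sum() * dens.bin_width == pytest.approx(1.0)

    def test_uniform_density_level(self):
        values = np.random.default_rng(14).uniform(10, 14, 200_000)
        dens = distribution_estimate(values, 0.5)
        interior = dens.density[1:-1]
        np.testing.assert_allclose(interior, 0.25, rtol=0.05)

    def test_bad_bin_width(self):
        with pytest.raises(ParameterError):
            distribution_estimate(np.arange(10.0), 0.0)
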