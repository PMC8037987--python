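"""Dihedral extraction and helix classification under both definitions."""

import numpy as np
import pytest

from ffentropy import (
    DihedralSeries,
    ParameterError,
    TrajectoryEnsemble,
    backbone_dihedrals,
    classify_pairwise_helix,
    classify_sequential_alpha,
    compare_temperatures,
    dihedral_angle,
    helical_fraction_profile,
    wrap_angle,
)
from ffentropy.helix import ALPHA, NONE_LABEL, PI, THREE_TEN
from ffentropy.synth import CANONICAL_DIHEDRALS, build_ideal_helix


def _series(phi_psi_rows, mask_terminals=True):
    """DihedralSeries for one frame from per-residue (phi, psi) tuples."""
    arr = np.array(phi_psi_rows, dtype=float)
    phi = arr[None, :, 0].copy()
    psi = arr[None, :, 1].copy()
    mask = np.ones_like(phi, dtype=bool)
    if mask_terminals:
        mask[:, 0] = mask[:, -1] = False
        phi[~mask] = np.nan
        psi[~mask] = np.nan
    return DihedralSeries(phi=phi, psi=psi, defined_mask=mask)


class TestDihedralAngle:
    def test_planar_zigzag_is_trans(self):
        pts = np.array(
            [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
             [1.0, -1.0, 0.0]]
        )
        assert dihedral_angle(*pts) == pytest.approx(180.0)

    def test_cis_is_zero(self):
        pts = np.array(
            [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
             [1.0, 1.0, 0.0]]
        )
        assert dihedral_angle(*pts) == pytest.approx(0.0, abs=1e-10)

    def test_mirror_image_negates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            a = dihedral_angle(*pts)
            b = dihedral_angle(*(pts * np.array([1.0, 1.0, -1.0])))
            assert b == pytest.approx(-a, abs=1e-9)

    def test_wrap_angle_range(self):
        vals = wrap_angle(np.array([-725.0, -180.0, 180.0, 540.0, 10.0]))
        assert np.all((vals > -180.0) & (vals <= 180.0))
        assert wrap_angle(-180.0) == 180.0


class TestBackboneDihedrals:
    @pytest.mark.parametrize("helix_type", sorted(CANONICAL_DIHEDRALS))
    def test_ideal_helix_round_trip(self, helix_type):
        model = build_ideal_helix(15, helix_type)
        traj = TrajectoryEnsemble(model.coordinates[None], model)
        series = backbone_dihedrals(traj)
        phi_c, psi_c = CANONICAL_DIHEDRALS[helix_type]
        interior = slice(1, 14)
        np.testing.assert_allclose(series.phi[0, interior], phi_c, atol=0.5)
        np.testing.assert_allclose(series.psi[0, interior], psi_c, atol=0.5)

    def test_terminals_masked(self, helix10):
        traj = TrajectoryEnsemble(helix10.coordinates[None], helix10)
        series = backbone_dihedrals(traj)
        assert not series.defined_mask[0, 0]
        assert not series.defined_mask[0, -1]
        assert np.isnan(series.phi[0, 0])
        assert np.isnan(series.psi[0, -1])

    def test_matches_mdtraj(self, helix15):
        """Cross-check the extractor against mdtraj's implementation."""
        import mdtraj

        rng = np.random.default_rng(1)
        coords = helix15.coordinates[None] + rng.normal(
            0, 0.05, (3,) + helix15.coordinates.shape
        )
        traj = TrajectoryEnsemble(coords, helix15)
        series = backbone_dihedrals(traj)
        mdt = mdtraj.Trajectory(
            coords / 10.0, helix15.to_mdtraj_topology()
        )
        _, phi = mdtraj.compute_phi(mdt)
        _, psi = mdtraj.compute_psi(mdt)
        np.testing.assert_allclose(
            series.phi[:, 1:], np.degrees(phi), atol=1e-3
        )
        np.testing.assert_allclose(
            series.psi[:, :-1], np.degrees(psi), atol=1e-3
        )


class TestSequentialAlpha:
    def test_all_residues_in_basin(self):
        series = _series([(-60.0, -45.0)] * 15)
        helical = classify_sequential_alpha(series)
        assert np.all(helical[0, 1:14])
        assert not helical[0, 0] and not helical[0, 14]

    def test_alternating_residues_never_helical(self):
        rows = [(-60.0, -45.0) if i % 2 == 0 else (-60.0, 100.0)
                for i in range(12)]
        helical = classify_sequential_alpha(_series(rows))
        assert not np.any(helical)

    def test_exact_run_boundary(self):
        rows = [(-60.0, 100.0)] * 10
        for i in (3, 4, 5):
            rows[i] = (-60.0, -45.0)
        helical = classify_sequential_alpha(_series(rows))
        assert np.array_equal(np.flatnonzero(helical[0]), [3, 4, 5])

    def test_two_residue_run_insufficient(self):
        rows = [(-60.0, 100.0)] * 10
        rows[4] = rows[5] = (-60.0, -45.0)
        assert not np.any(classify_sequential_alpha(_series(rows)))

    def test_undefined_residue_breaks_run(self):
        rows = [(-60.0, -45.0)] * 9
        series = _series(rows)
        series.defined_mask[0, 4] = False
        series.phi[0, 4] = np.nan
        helical = classify_sequential_alpha(series)
        assert not helical[0, 4]
        assert np.all(helical[0, 1:4]) and np.all(helical[0, 5:8])


class TestPairwiseHelix:
    @pytest.mark.parametrize(
        "psi_i,phi_next,expected",
        [
            (-50.0, -55.0, ALPHA),       # s = -105, window center
            (-70.0, -55.0, PI),          # s = -125
            (-30.0, -45.0, THREE_TEN),   # s = -75
            (-60.0, -55.0, ALPHA),       # s = -115, shared boundary -> alpha
            (-60.1, -55.0, PI),          # s just below -115 -> pi
            (-40.0, -55.0, ALPHA),       # s = -95, alpha upper edge
            (-30.0, -55.0, THREE_TEN),   # s = -85, 3-10 lower edge
            (-10.0, -55.0, THREE_TEN),   # s = -65, 3-10 upper edge
            (-80.0, -55.0, PI),          # s = -135, pi lower edge
            (-9.9, -55.0, NONE_LABEL),   # s just above -65
            (-80.1, -55.0, NONE_LABEL),  # s just below -135
        ],
    )
    def test_window_assignment(self, psi_i, phi_next, expected):
        # 7 residues; probe pair sits mid-chain, clear of the excluded ends
        rows = [(0.0, 100.0)] * 7
        rows[3] = (0.0, psi_i)
        rows[4] = (phi_next, 100.0)
        labels = classify_pairwise_helix(_series(rows))
        assert labels[0, 3] == expected

    @pytest.mark.parametrize("helix_type,code", [
        ("alpha", ALPHA), ("pi", PI), ("three_ten", THREE_TEN),
    ])
    def test_canonical_helix_sums(self, helix_type, code):
        phi_c, psi_c = CANONICAL_DIHEDRALS[helix_type]
        labels = classify_pairwise_helix(_series([(phi_c, psi_c)] * 10))
        # defined pairs span residues 1..7; ends excluded leaves 2..6
        assert np.all(labels[0, 2:7] == code)
        assert labels[0, 1] == NONE_LABEL and labels[0, 7] == NONE_LABEL

    def test_first_last_pair_excluded_follows_mask(self):
        rows = [(-55.0, -50.0)] * 8
        series = _series(rows, mask_terminals=False)
        labels = classify_pairwise_helix(series)
        assert labels[0, 0] == NONE_LABEL
        assert labels[0, 6] == NONE_LABEL
        assert np.all(labels[0, 1:6] == ALPHA)

    def test_windows_never_overlap(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(-180.0, 180.0, 100_000)
        in_pi = (s >= -135.0) & (s < -115.0)
        in_alpha = (s >= -115.0) & (s <= -95.0)
        in_310 = (s >= -85.0) & (s <= -65.0)
        assert np.all(in_pi.astype(int) + in_alpha + in_310 <= 1)

    def test_needs_four_residues(self):
        with pytest.raises(ParameterError):
            classify_pairwise_helix(_series([(0.0, 0.0)] * 3,
                                            mask_terminals=False))


class TestFractionProfile:
    def test_all_alpha(self):
        labels = np.full((20, 5), ALPHA)
        profile = helical_fraction_profile(labels)
        np.testing.assert_allclose(profile.alpha, 100.0)
        np.testing.assert_allclose(profile.combined, 100.0)

    def test_half_pi(self):
        labels = np.zeros((10, 4), dtype=int)
        labels[:5] = PI
        profile = helical_fraction_profile(labels)
        np.testing.assert_allclose(profile.pi, 50.0)
        np.testing.assert_allclose(profile.combined, 50.0)
        np.testing.assert_allclose(profile.alpha, 0.0)

    def test_combined_is_sum_of_disjoint_types(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, size=(200, 9))
        profile = helical_fraction_profile(labels)
        np.testing.assert_allclose(
            profile.combined,
            profile.alpha + profile.pi + profile.three_ten,
            atol=1e-9,
        )
        assert np.all(profile.combined >= np.maximum(
            profile.alpha, np.maximum(profile.pi, profile.three_ten)
        ))

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, size=(50, 6))
        p1 = helical_fraction_profile(labels)
        p2 = helical_fraction_profile(labels[rng.permutation(50)])
        np.testing.assert_allclose(p1.combined, p2.combined)

    def test_sequential_below_combined_on_random_coil(self):
        """Uniform-torus dihedrals: run-of-3 alpha is rarer than any pair hit."""
        rng = np.random.default_rng(5)
        n_frames, n_res = 10_000, 12
        phi = rng.uniform(-180.0, 180.0, (n_frames, n_res))
        psi = rng.uniform(-180.0, 180.0, (n_frames, n_res))
        mask = np.ones_like(phi, dtype=bool)
        series = DihedralSeries(phi=phi, psi=psi, defined_mask=mask)
        profile = helical_fraction_profile(
            classify_pairwise_helix(series),
            classify_sequential_alpha(series),
        )
        interior = slice(2, n_res - 3)
        assert profile.sequential_alpha[interior].mean() < \
            profile.combined[interior].mean()


class TestCompareTemperatures:
    def test_identical_profiles_zero(self):
        labels = np.random.default_rng(6).integers(0, 4, (30, 5))
        a = helical_fraction_profile(labels, temperature_label="300K")
        b = helical_fraction_profile(labels, temperature_label="360K")
        diff = compare_temperatures(a, b)
        for col in diff.columns:
            if col.startswith("d_"):
                np.testing.assert_allclose(diff[col], 0.0)

    def test_uniform_offset(self):
        labels_a = np.zeros((20, 5), dtype=int)
        labels_a[:10] = ALPHA  # 50%
        labels_b = np.zeros((20, 5), dtype=int)
        labels_b[:9] = ALPHA   # 45%
        a = helical_fraction_profile(labels_a)
        b = helical_fraction_profile(labels_b)
        diff = compare_temperatures(a, b)
        np.testing.assert_allclose(diff["d_alpha_pct"], 5.0)
        assert diff.attrs["summary_mean_abs_change"]["alpha"] == \
            pytest.approx(5.0)

    def test_length_mismatch(self):
        a = helical_fraction_profile(np.zeros((5, 4), dtype=int))
        b = helical_fraction_profile(np.zeros((5, 6), dtype=int))
        with pytest.raises(ParameterError):
            compare_temperatures(a, b)
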