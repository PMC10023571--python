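"""Projection, reconstruction, symmetrization and the symmetry search."""

import numpy as np
import pandas as pd
import pytest

from helixsub.core import HelicalLattice, VolumeGrid, correlation, nrmse, substream
from helixsub.helix import (
    CylindricalCache,
    backproject,
    box_physical_size,
    extract_segments,
    pitch,
    project,
    project_real,
    reconstruct,
    symmetrize,
    symmetry_score,
    symmetry_score_cartesian,
    symmetry_search,
)
from helixsub.scene import (
    assemble_filament,
    project_analytic,
    render_volume,
    sample_pitch_profile,
)


class TestGeometryArithmetic:
    @pytest.mark.parametrize("box,px,expected", [
        (600, 1.35, 810.0),  # full extraction box
        (300, 1.35, 405.0),  # recentered subparticle box
        (1, 1.0, 1.0),
    ])
    def test_box_physical_size(self, box, px, expected):
        assert box_physical_size(box, px) == pytest.approx(expected)

    def test_pitch_at_minimum_twist(self):
        # rise 26.75 Å at the lower twist bound gives the upper pitch bound
        assert pitch(46.9, 26.75) == pytest.approx(205.3, abs=0.05)

    def test_pitch_at_maximum_rise(self):
        assert pitch(47.3, 28.2) == pytest.approx(214.6, abs=0.05)

    def test_pitch_of_full_turn_per_unit(self):
        assert pitch(360.0, 4.75) == pytest.approx(4.75)

    def test_pitch_rejects_zero_twist(self):
        with pytest.raises(ValueError):
            pitch(0.0, 26.75)


class TestProject:
    def test_identity_pose_of_axial_blob_is_circular(self):
        from helixsub.scene import ProtomerModel, build_protomer

        blob = build_protomer(ProtomerModel([(np.zeros(3), 9.0, 1.0)], "C1"), 48, 3.0)
        img = project(blob, (0.0, 0.0, 0.0))
        assert np.allclose(img, img.T, atol=1e-6 * img.max())

    @pytest.mark.parametrize("pose", [(30, 60, 20), (123, 87, 245), (0, 90, 10)])
    def test_projection_integral_equals_volume_integral(self, smooth_compact_volume, pose):
        img = project(smooth_compact_volume, pose)
        assert img.sum() == pytest.approx(smooth_compact_volume.data.sum(), rel=1e-6)

    @pytest.mark.parametrize("pose", [(30, 60, 20), (123, 87, 245), (77, 13, 301)])
    def test_fourier_slice_agrees_with_analytic_oracle(self, protomer,
                                                       protomer_volume, pose):
        blobs = [(c, s, w) for c, s, w in protomer.blobs]
        fs = project(protomer_volume, pose)
        oracle = project_analytic(blobs, pose, 48, 3.0)
        assert nrmse(fs, oracle) < 0.02

    @pytest.mark.parametrize("pose", [(30, 60, 20), (0, 90, 10)])
    def test_fourier_slice_agrees_with_real_space_sum(self, protomer_volume, pose):
        fs = project(protomer_volume, pose)
        rs = project_real(protomer_volume, pose)
        assert nrmse(fs, rs) < 0.02

    def test_adjointness_of_project_and_backproject(self, smooth_compact_volume):
        """<project(V), I> should equal <V, backproject(I)> within 1%."""
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        pose = (40.0, 75.0, 15.0)
        img = gaussian_filter(rng.normal(size=(48, 48)), 3.0)
        lhs = float(np.sum(project(smooth_compact_volume, pose) * img))
        bp = backproject(img, pose, 3.0)
        rhs = float(np.sum(smooth_compact_volume.data * bp.data))
        assert lhs == pytest.approx(rhs, rel=0.01)


class TestReconstruct:
    def test_single_identity_image_back_smears(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.normal(size=(32, 32)), 3.0)
        recs = pd.DataFrame([{"rot": 0.0, "tilt": 0.0, "psi": 0.0, "x": 0.0, "y": 0.0}])
        vol = reconstruct(img[None], recs, 3.0)
        zsum = vol.data.sum(axis=0)
        assert correlation(zsum, img) > 0.98

    def test_uniform_side_views_recover_volume(self, protomer_volume):
        from helixsub.spa import fsc

        poses = [(r, 90.0, 0.0) for r in np.arange(0, 360, 2.0)]
        stack = np.stack([project(protomer_volume, p) for p in poses])
        recs = pd.DataFrame([{"rot": r, "tilt": t, "psi": s, "x": 0.0, "y": 0.0}
                             for r, t, s in poses])
        rec = reconstruct(stack, recs, 3.0)
        assert correlation(rec.data, protomer_volume.data) > 0.95
        curve = fsc(rec, protomer_volume)
        half = len(curve.values) // 2
        assert np.all(curve.values[:half] > 0.9)

    def test_duplicating_particles_changes_nothing(self, protomer_volume):
        poses = [(r, 90.0, 0.0) for r in np.arange(0, 360, 30.0)]
        stack = np.stack([project(protomer_volume, p) for p in poses])
        recs = pd.DataFrame([{"rot": r, "tilt": t, "psi": s, "x": 0.0, "y": 0.0}
                             for r, t, s in poses])
        a = reconstruct(stack, recs, 3.0)
        b = reconstruct(np.concatenate([stack, stack]),
                        pd.concat([recs, recs], ignore_index=True), 3.0)
        assert np.allclose(a.data, b.data, atol=1e-4 * np.abs(a.data).max())

    def test_empty_stack_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct(np.zeros((0, 16, 16)), pd.DataFrame(), 3.0)


class TestSymmetrize:
    def test_idempotent_in_central_span(self, constant_filament_volume):
        # averaging is a true projector only away from the filament ends,
        # so idempotence is asserted over the central z span
        lat = HelicalLattice(47.2, 26.75, "D1")
        once = symmetrize(constant_filament_volume, lat)
        twice = symmetrize(once, lat)
        n = constant_filament_volume.n
        sl = slice(n // 4, 3 * n // 4)
        assert correlation(once.data[sl], twice.data[sl]) > 0.999

    def test_exactly_symmetric_input_unchanged(self, constant_filament_volume):
        lat = HelicalLattice(47.2, 26.75, "D1")
        out = symmetrize(constant_filament_volume, lat)
        # compare inside the central z span only (ends are averaged down)
        n = constant_filament_volume.n
        sl = slice(n // 4, 3 * n // 4)
        assert correlation(out.data[sl], constant_filament_volume.data[sl]) > 0.99

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        noise = VolumeGrid(rng.normal(size=(64, 64, 64)), 4.5)
        out = symmetrize(noise, HelicalLattice(47.2, 26.75, "C1"))
        n = 64
        sl = slice(n // 4, 3 * n // 4)
        assert out.data[sl].var() < noise.data[sl].var()

    def test_symmetrization_never_worsens_score(self, constant_filament_volume):
        lat = HelicalLattice(47.2, 26.75, "D1")
        before = symmetry_score(constant_filament_volume, lat.twist, lat.rise,
                                rise_max=30.0)
        after = symmetry_score(symmetrize(constant_filament_volume, lat),
                               lat.twist, lat.rise, rise_max=30.0)
        assert after <= before * 1.01

    def test_oversized_rise_rejected(self, constant_filament_volume):
        with pytest.raises(ValueError, match="z span"):
            symmetrize(constant_filament_volume, HelicalLattice(47.2, 100.0, "C1"),
                       z_span=50.0)


class TestSymmetryScore:
    def test_zero_volume_scores_zero(self):
        v = VolumeGrid(np.zeros((48, 48, 48)), 4.5)
        assert symmetry_score(v, 47.0, 26.0, rise_max=30.0) == 0.0

    def test_generator_parameters_beat_offset(self, constant_filament_volume):
        good = symmetry_score(constant_filament_volume, 47.2, 26.75, rise_max=30.0)
        bad = symmetry_score(constant_filament_volume, 48.2, 26.75, rise_max=30.0)
        assert good < bad

    def test_equivariant_under_axial_rotation(self, constant_filament_volume):
        from helixsub.core import rot_z, rotate_volume

        rotated = VolumeGrid(
            rotate_volume(constant_filament_volume.data, rot_z(33.0), order=3), 4.5
        )
        a = symmetry_score(constant_filament_volume, 47.2, 26.75, rise_max=30.0)
        b = symmetry_score(rotated, 47.2, 26.75, rise_max=30.0)
        assert b == pytest.approx(a, rel=0.05)

    def test_cylindrical_matches_cartesian_oracle(self, constant_filament_volume):
        for tw, ri in [(47.2, 26.75), (46.0, 25.0), (48.5, 28.5)]:
            cyl = symmetry_score(constant_filament_volume, tw, ri, rise_max=30.0)
            cart = symmetry_score_cartesian(constant_filament_volume, tw, ri,
                                            rise_max=30.0)
            assert cyl == pytest.approx(cart, rel=0.15)


class TestSymmetrySearch:
    def test_single_point_grid_is_argmin(self, constant_filament_volume):
        surf = symmetry_search(constant_filament_volume, np.array([47.0]),
                               np.array([26.5]))
        assert surf.argmin == (47.0, 26.5)

    def test_recovers_generator_parameters(self, constant_filament_volume):
        tgrid = np.arange(46.0, 48.5 + 1e-9, 0.1)
        rgrid = np.arange(25.5, 28.0 + 1e-9, 0.05)
        surf = symmetry_search(constant_filament_volume, tgrid, rgrid,
                               start=(47.3, 26.7), z_span_angstrom=170.0)
        assert surf.argmin[0] == pytest.approx(47.2, abs=0.1 + 1e-9)
        assert surf.argmin[1] == pytest.approx(26.75, abs=0.05 + 1e-9)

    def test_variable_pitch_basin_broader_than_constant(self, protomer,
                                                        constant_filament_volume):
        tgrid = np.arange(46.0, 48.5 + 1e-9, 0.1)
        rgrid = np.arange(25.0, 28.5 + 1e-9, 0.05)
        kw = dict(start=(47.3, 26.7), z_span_angstrom=170.0)
        const = symmetry_search(constant_filament_volume, tgrid, rgrid, **kw)
        rng = substream(2, "walk")
        prof = sample_pitch_profile((46.9, 47.7), (25.2, 28.2), "random_walk", 10, rng)
        wobbly = render_volume(assemble_filament(protomer, prof, 45.0), 96, 4.5,
                               clip_tolerance=1.0)
        var = symmetry_search(wobbly, tgrid, rgrid, **kw)
        assert var.basin_size() > const.basin_size()

    def test_empty_grid_rejected(self, constant_filament_volume):
        with pytest.raises(ValueError, match="nonempty"):
            symmetry_search(constant_filament_volume, np.array([]), np.array([26.0]))


class TestExtractSegments:
    def test_straight_trace_segment_count_and_psi(self):
        mic = np.zeros((128, 256))
        mic[64, :] = 1.0
        trace = np.array([[10.0, 64.0], [230.0, 64.0]])  # horizontal
        step = 22.0  # Å; at 1 Å/px trace length 220 px -> 11 segments
        stack, recs = extract_segments(mic, trace, 32, step, 1.0)
        assert len(stack) == 11
        assert np.allclose(recs["psi_prior"], 0.0)

    def test_short_trace_warns_and_returns_empty(self):
        mic = np.zeros((64, 64))
        trace = np.array([[10.0, 32.0], [14.0, 32.0]])
        with pytest.warns(UserWarning, match="shorter"):
            stack, recs = extract_segments(mic, trace, 32, 10.0, 1.0)
        assert len(stack) == 0 and len(recs) == 0

    def test_segments_match_ground_truth_projection(self, protomer):
        """Segments of a noiseless rendered filament correlate with the
        analytic projection at the recorded position."""
        prof = sample_pitch_profile((47.2, 47.2), (26.75, 26.75), "constant", 10,
                                    np.random.default_rng(0))
        placed = assemble_filament(protomer, prof, 45.0)
        # micrograph: filament lying along x (pose rot=0, tilt=90, psi=0)
        n_mic = 160
        img = project_analytic(placed.blob_list(), (0.0, 90.0, 0.0), n_mic, 3.0)
        trace = np.array([[40.0, 80.0], [120.0, 80.0]])
        stack, recs = extract_segments(img, trace, 48, 26.75, 3.0)
        assert len(stack) >= 5
        for i in range(len(stack)):
            rec = recs.iloc[i]
            # the helix axis maps onto image x at this pose, so recentring the
            # box at trace position x corresponds to an axial (z) offset
            ref = project_analytic(
                placed.blob_list(), (0.0, 90.0, 0.0), 48, 3.0,
                extra_offset=np.array(
                    [0.0, 0.0, -(rec["x"] - n_mic / 2) * 3.0]
                ),
            )
            assert correlation(stack[i], ref) > 0.9
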