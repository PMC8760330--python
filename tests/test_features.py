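"""Twist-dipole and protrusion-dot detection, quantification and linking."""

import numpy as np
import pytest

from forcekit import (
    BandpassSpec,
    DisplacementMap,
    ForceFeature,
    StressMap,
    SyntheticScene,
    classify_cell_protrusion_status,
    contraction_force,
    detect_protrusion_dots,
    detect_twists,
    displacement_to_stress,
    fourier_bandpass,
    indentation_force,
    link_features,
    make_fine_structure_scene,
    render_displacement_map,
)
from forcekit.features import FeatureTrack
from conftest import single_dipole_scene, single_protrusion_scene

SPEC = BandpassSpec(0.1, 0.6, 0.05)


def zero_map():
    return DisplacementMap(np.zeros((64, 64)), 0.5)


class TestDetectTwists:
    def test_zero_map_empty(self):
        assert detect_twists(zero_map()) == []

    def test_unfiltered_input_rejected(self):
        m = DisplacementMap(np.full((32, 32), 50.0), 0.5)
        with pytest.raises(ValueError, match="bandpass"):
            detect_twists(m)

    def test_single_1nn_dipole_round_trip(self, substrate):
        m = render_displacement_map(single_dipole_scene(1.0), substrate, 0)
        feats = detect_twists(m)
        assert len(feats) == 1
        f = feats[0]
        assert f.twist_amplitude_nm == pytest.approx(6.6, rel=0.05)
        assert abs(f.centroid_um[0] - 24.0) <= substrate.pixel_size_um
        assert abs(f.centroid_um[1] - 24.0) <= substrate.pixel_size_um
        assert f.force == pytest.approx(1.0, rel=0.05)

    def test_two_well_separated_dipoles(self, substrate):
        a = single_dipole_scene(1.0, pos=(14.0, 14.0))
        b = single_dipole_scene(2.0, pos=(34.0, 34.0), axis_angle=1.0)
        scene = SyntheticScene(
            (48.0, 48.0), 5.0, 1, a.cells + b.cells, noise_sd_nm=0.0
        )
        m = render_displacement_map(scene, substrate, 0)
        feats = detect_twists(m)
        assert len(feats) == 2
        # deterministic ordering: descending amplitude
        assert feats[0].twist_amplitude_nm > feats[1].twist_amplitude_nm

    def test_amplitude_survives_default_bandpass_within_5pct(self, substrate):
        m = render_displacement_map(single_dipole_scene(2.0), substrate, 0)
        filt = fourier_bandpass(m, SPEC)
        f = detect_twists(filt)[0]
        assert f.twist_amplitude_nm == pytest.approx(13.2, rel=0.05)

    def test_translation_equivariance(self, substrate):
        m = render_displacement_map(single_dipole_scene(1.0), substrate, 0)
        shifted = DisplacementMap(np.roll(m.values, (6, -4), axis=(0, 1)), 0.5)
        f0 = detect_twists(m)[0]
        f1 = detect_twists(shifted)[0]
        dx = f1.centroid_um[0] - f0.centroid_um[0]
        dy = f1.centroid_um[1] - f0.centroid_um[1]
        assert dx == pytest.approx(-4 * 0.5, abs=1e-6)
        assert dy == pytest.approx(6 * 0.5, abs=1e-6)

    def test_protrusion_map_yields_no_twists(self, substrate):
        # the dot's pulling ring is too shallow to pair as a lobe
        m = render_displacement_map(single_protrusion_scene(80.0), substrate, 0)
        assert detect_twists(m) == []


class TestContractionForce:
    @pytest.mark.parametrize(
        "amplitude,expected", [(6.6, 1.0), (0.0, 0.0), (13.2, 2.0)]
    )
    def test_linear_calibration(self, amplitude, expected):
        assert contraction_force(amplitude) == pytest.approx(expected, rel=1e-12)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            contraction_force(-1.0)


class TestDetectProtrusionDots:
    def test_zero_map_empty(self):
        assert detect_protrusion_dots(zero_map()) == []

    def test_degenerate_diameter_range(self):
        with pytest.raises(ValueError, match="degenerate"):
            detect_protrusion_dots(zero_map(), core_diameter_range_um=(4.0, 1.0))

    def test_single_dot_centroid_within_one_pixel(self, substrate):
        for pos in ((24.0, 24.0), (23.87, 24.33)):
            m = render_displacement_map(
                single_protrusion_scene(50.0, pos=pos), substrate, 0
            )
            feats = detect_protrusion_dots(m)
            assert len(feats) == 1
            assert abs(feats[0].centroid_um[0] - pos[0]) <= 0.5
            assert abs(feats[0].centroid_um[1] - pos[1]) <= 0.5

    def test_rendered_dipole_yields_no_dots(self, substrate):
        m = render_displacement_map(single_dipole_scene(2.0), substrate, 0)
        assert detect_protrusion_dots(m) == []
        filt = fourier_bandpass(m, SPEC)
        assert detect_protrusion_dots(filt) == []

    def test_noiseless_precision_and_recall_are_one(self, substrate):
        # two dots and one dipole, all in range and well separated
        a = single_protrusion_scene(50.0, pos=(12.0, 12.0))
        b = single_protrusion_scene(70.0, pos=(36.0, 36.0))
        c = single_dipole_scene(2.0, pos=(36.0, 12.0))
        scene = SyntheticScene(
            (48.0, 48.0), 5.0, 1, a.cells + b.cells + c.cells, noise_sd_nm=0.0
        )
        m = render_displacement_map(scene, substrate, 0)
        dots = detect_protrusion_dots(m)
        assert len(dots) == 2
        found = sorted(f.centroid_um for f in dots)
        assert np.allclose(found, [(12.0, 12.0), (36.0, 36.0)], atol=0.5)
        twists = detect_twists(m)
        assert len(twists) == 1
        assert np.allclose(twists[0].centroid_um, (36.0, 12.0), atol=0.5)


class TestIndentationForce:
    def _feature(self, mask):
        return ForceFeature(
            kind="protrusion_dot",
            centroid_um=(2.0, 2.0),
            core_area_um2=float(mask.sum()),
            core_mask=mask,
        )

    def test_uniform_10pa_over_2um2(self):
        mask = np.zeros((20, 20), bool)
        mask[9:11, 9:10] = True  # 2 px at 1 um -> 2 um^2
        stress = np.zeros((20, 20))
        stress[mask] = 10.0
        f = self._feature(mask)
        got = indentation_force(f, StressMap(stress, 1.0), 4.0, core_dilation_um=0.0)
        assert got == pytest.approx(20.0, rel=1e-12)

    def test_below_threshold_gives_zero(self):
        mask = np.zeros((20, 20), bool)
        mask[9:11, 9:10] = True
        stress = np.zeros((20, 20))
        stress[mask] = 3.0
        f = self._feature(mask)
        assert indentation_force(f, StressMap(stress, 1.0), 4.0, 0.0) == 0.0

    def test_kind_and_alignment_checks(self):
        mask = np.ones((4, 4), bool)
        f = self._feature(mask)
        with pytest.raises(ValueError, match="aligned"):
            indentation_force(f, StressMap(np.zeros((5, 5)), 1.0))
        twist = ForceFeature(kind="twist_dipole", centroid_um=(0, 0))
        with pytest.raises(ValueError, match="protrusion_dot"):
            indentation_force(twist, StressMap(np.zeros((4, 4)), 1.0))

    def test_oscillating_force_recovered_noiseless(self, substrate):
        # sinusoid between 40 and 80 pN through the full inversion chain
        from forcekit import ProtrusionSource, SyntheticCell

        n = 12
        prot = ProtrusionSource.sinusoidal(
            n, 5.0, peak_pn=80.0, trough_pn=40.0, period_s=30.0
        )
        cell = SyntheticCell(
            trajectory_um=np.tile([24.0, 24.0], (n, 1)),
            body_radius_um=12.0,
            protrusions=[prot],
            central_indentation_amplitude_nm=0.0,
        )
        scene = SyntheticScene((48.0, 48.0), 5.0, n, [cell], noise_sd_nm=0.0)
        for frame in range(n):
            m = render_displacement_map(scene, substrate, frame)
            s = displacement_to_stress(m, substrate, tikhonov=1e-9)
            dot = detect_protrusion_dots(m)[0]
            rec = indentation_force(dot, s, None, core_dilation_um=1.0)
            assert rec == pytest.approx(prot.force_at(frame), rel=0.02)


class TestLinking:
    def _feat(self, x, y, frame=0, force=10.0):
        return ForceFeature(
            kind="protrusion_dot", centroid_um=(x, y), frame=frame, force=force
        )

    def test_stationary_feature_single_track(self):
        frames = [[self._feat(5.0, 5.0)] for _ in range(10)]
        tracks = link_features(frames, 2.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_jump_beyond_link_distance_splits_track(self):
        frames = [[self._feat(5.0, 5.0)]] * 5 + [[self._feat(15.0, 5.0)]] * 5
        tracks = link_features(frames, 2.0)
        assert len(tracks) == 2
        assert [len(t) for t in tracks] == [5, 5]

    def test_two_oscillating_dots_no_identity_swap(self, substrate):
        from forcekit import ProtrusionSource, SyntheticCell

        n = 6
        cells = []
        for x, phase in ((16.0, 0.0), (26.0, np.pi)):
            prot = ProtrusionSource.sinusoidal(
                n, 5.0, peak_pn=80.0, trough_pn=40.0, period_s=15.0, phase=phase
            )
            cells.append(
                SyntheticCell(
                    trajectory_um=np.tile([x, 24.0], (n, 1)),
                    body_radius_um=12.0,
                    protrusions=[prot],
                    central_indentation_amplitude_nm=0.0,
                )
            )
        scene = SyntheticScene((48.0, 48.0), 5.0, n, cells, noise_sd_nm=0.0)
        per_frame = []
        for f in range(n):
            m = render_displacement_map(scene, substrate, f)
            per_frame.append(detect_protrusion_dots(m))
        tracks = link_features(per_frame, 2.0)
        assert len(tracks) == 2
        for tr in tracks:
            xs = [f.centroid_um[0] for f in tr.features]
            assert max(xs) - min(xs) < 1.0  # each track stays on its dot

    def test_non_monotone_frame_times_rejected(self):
        f0 = self._feat(1.0, 1.0)
        f0.frame_time_s = 10.0
        f1 = self._feat(1.0, 1.0)
        f1.frame_time_s = 5.0
        with pytest.raises(ValueError, match="increasing"):
            link_features([[f0], [f1]], 2.0)

    def test_oscillation_period_estimate(self):
        track = FeatureTrack(0)
        t = np.arange(40)
        for i, v in enumerate(60 + 20 * np.sin(2 * np.pi * t / 8.0)):
            track.features.append(self._feat(0, 0, frame=i, force=v))
        # period 8 frames x 5 s = 40 s
        assert track.oscillation_period_s(5.0) == pytest.approx(40.0, rel=0.05)


class TestClassification:
    def test_persistent_track_positive(self):
        tr = FeatureTrack(0, [ForceFeature("protrusion_dot", (0, 0), frame=i) for i in range(20)])
        assert classify_cell_protrusion_status({1: [tr]}, 5) == {1: True}

    def test_no_dots_negative(self):
        assert classify_cell_protrusion_status({1: []}, 3) == {1: False}

    def test_population_fraction_recovered_exactly(self, substrate):
        # 2 of 3 cells carry a persistent dot
        spec = SPEC
        status = {}
        for cell_id, with_dot in ((1, True), (2, True), (3, False)):
            scene = make_fine_structure_scene(
                n_dots=1 if with_dot else 0,
                n_dipoles=1,
                n_frames=6,
                noise_sd_nm=0.0,
                seed=cell_id,
            )
            per_frame = []
            for f in range(6):
                m = render_displacement_map(scene, substrate, f)
                per_frame.append(detect_protrusion_dots(fourier_bandpass(m, spec)))
            tracks = link_features(per_frame, 2.0)
            status[cell_id] = classify_cell_protrusion_status({cell_id: tracks}, 3)[cell_id]
        assert sum(status.values()) == 2


class TestForceScaleSeparation:
    def test_horizontal_forces_dwarf_vertical(self, substrate):
        # nN-scale twists vs pN-scale dots in a default fine scene:
        # order-of-magnitude separation, not a fixed number
        scene = make_fine_structure_scene(
            n_dots=1, n_dipoles=2, n_frames=1, noise_sd_nm=0.0, seed=0
        )
        m = render_displacement_map(scene, substrate, 0)
        filt = fourier_bandpass(m, SPEC)
        twists = detect_twists(filt)
        dots = detect_protrusion_dots(filt)
        stress = displacement_to_stress(filt, substrate, tikhonov=1e-9)
        assert twists and dots
        mean_twist_pn = np.mean([t.force for t in twists]) * 1000.0
        mean_dot_pn = np.mean(
            [indentation_force(d, stress) for d in dots]
        )
        assert mean_twist_pn / mean_dot_pn > 10.0
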