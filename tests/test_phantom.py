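import numpy as np
import pytest

from depotmetry.errors import ConfigError
from depotmetry.phantom import (DepotSpec, PhantomSpec, PressureSpec,
                                SeptaSpec, add_noise, cylinder_analytic,
                                generate_depot_sequence,
                                generate_pressure_trace,
                                generate_septa_background, generate_session,
                                generate_cannula, impulse_schedule,
                                phantom_spec_from_dict, phantom_spec_to_dict,
                                septal_wall_mask, sphere_analytic)
from depotmetry.morpho import compact_surface


class TestSeptaBackground:
    def test_deterministic(self, tiny_spec):
        a = generate_septa_background(tiny_spec, seed=42).data
        b = generate_septa_background(tiny_spec, seed=42).data
        np.testing.assert_array_equal(a, b)

    def test_two_intensity_modes_in_hypodermis(self, tiny_spec):
        bg = generate_septa_background(tiny_spec, seed=42).data
        hypo = bg[tiny_spec.dermis_hypodermis_z:]
        s = tiny_spec.septa
        n_wall = np.sum(hypo == s.wall_intensity)
        n_lob = np.sum(hypo == s.lobule_intensity)
        assert n_wall + n_lob == hypo.size
        assert n_wall > 0.02 * hypo.size
        assert n_lob > 0.3 * hypo.size

    def test_single_lobule_has_no_walls(self, tiny_spec):
        spec = PhantomSpec(
            grid_shape=tiny_spec.grid_shape, n_frames=3,
            septa=SeptaSpec(n_lobules=1),
            epidermis_z=6, dermis_hypodermis_z=16)
        assert not septal_wall_mask(spec, seed=0).any()

    def test_zero_lobules_rejected(self, tiny_spec):
        spec = PhantomSpec(grid_shape=tiny_spec.grid_shape, n_frames=3,
                           septa=SeptaSpec(n_lobules=0),
                           epidermis_z=6, dermis_hypodermis_z=16)
        with pytest.raises(ConfigError):
            septal_wall_mask(spec, seed=0)


class TestDepotSequence:
    def test_references_empty_then_nested_growth(self, tiny_session):
        _, gt = tiny_session
        assert not gt.masks[0].any() and not gt.masks[1].any()
        for a, b in zip(gt.masks[2:], gt.masks[3:]):
            assert np.all(b[a])  # mask(t) subset of mask(t+1)

    def test_septal_growth_prefers_walls(self, tiny_session):
        _, gt = tiny_session
        assert gt.wall_fraction[-1] >= 0.8

    def test_sphere_analytic_ground_truth(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 64), n_frames=5,
            depot=DepotSpec(shape="sphere", radius_start_vox=8,
                            radius_end_vox=12),
            epidermis_z=6, dermis_hypodermis_z=16, noise_gaussian_sd=0.0,
        )
        _, gt = generate_depot_sequence(spec, seed=0)
        # voxel-counted volume converges to the closed form within 3/r
        for m, v, r in zip(gt.masks[2:], gt.analytic_volume_mm3[2:],
                           gt.size_parameter_vox[2:]):
            vox_mm3 = (spec.voxel_size_um / 1000.0) ** 3
            v_count = m.sum() * vox_mm3
            assert v_count == pytest.approx(v, rel=3.0 / r)

    def test_cylinder_iod_grows_as_cube_root_of_length(self):
        # closed-form IoD of a capped cylinder vs equal-volume sphere
        iods = []
        for length in (50, 100, 200):
            v, s = cylinder_analytic(3.0, length, 17.0)
            iods.append(s / compact_surface(v))
        assert iods[0] < iods[1] < iods[2]
        slope = np.polyfit(np.log([50, 100, 200]), np.log(iods), 1)[0]
        assert 0.28 < slope < 0.39

    def test_full_determinism(self, tiny_spec):
        s1, g1 = generate_session(tiny_spec, seed=7)
        s2, g2 = generate_session(tiny_spec, seed=7)
        for a, b in zip(s1.frames, s2.frames):
            np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(s1.pressure.pressure_mbar,
                                      s2.pressure.pressure_mbar)
        for a, b in zip(g1.masks, g2.masks):
            np.testing.assert_array_equal(a, b)

    def test_spec_yaml_roundtrip(self, tiny_spec):
        d = phantom_spec_to_dict(tiny_spec)
        spec2 = phantom_spec_from_dict(d)
        assert phantom_spec_to_dict(spec2) == d


class TestCannula:
    def test_no_schedule_no_bubbles(self, tiny_spec):
        flags = [generate_cannula(tiny_spec, i)[2] for i in range(1, 9)]
        assert flags == [False] * 8

    def test_bubble_schedule_pattern(self, tiny_spec):
        spec = PhantomSpec(grid_shape=tiny_spec.grid_shape, n_frames=9,
                           bubble_frames=((4, 6),),
                           epidermis_z=6, dermis_hypodermis_z=16)
        flags = [generate_cannula(spec, i)[2] for i in range(1, 10)]
        assert flags == [False] * 3 + [True] * 3 + [False] * 3
        mask, bubble, _ = generate_cannula(spec, 5)
        assert bubble.any() and np.all(mask[bubble])

    def test_occlusion_freezes_lumen_and_delays_depot(self):
        spec = PhantomSpec(grid_shape=(48, 64, 64), n_frames=16,
                           occlusion_until_frame=13,
                           depot=DepotSpec(voxels_per_impulse=200),
                           epidermis_z=6, dermis_hypodermis_z=16,
                           noise_gaussian_sd=0.0, even_frame_shift_vox=0.0)
        frames, gt = generate_depot_sequence(spec, seed=3)
        for i in range(13):
            assert not gt.masks[i].any()
        assert gt.masks[13].any()
        # lumen content identical over the occluded frames (odd parity:
        # even frames carry the sub-voxel tilt in the general case)
        base = frames[0].data
        for f in frames[2:13:2]:
            np.testing.assert_array_equal(f.data, base)


class TestNoise:
    def test_sd_zero_is_identity(self, tiny_spec):
        bg = generate_septa_background(tiny_spec, seed=1)
        out = add_noise(bg, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, bg.data)

    def test_deterministic_per_seed_and_frame(self, tiny_spec):
        bg = generate_septa_background(tiny_spec, seed=1)
        a = add_noise(bg, 5.0, seed=9).data
        b = add_noise(bg, 5.0, seed=9).data
        np.testing.assert_array_equal(a, b)
        c = add_noise(bg, 5.0, seed=10).data
        assert not np.array_equal(a, c)

    def test_sample_sd_matches_request(self):
        spec = PhantomSpec(grid_shape=(100, 100, 100), n_frames=3,
                           epidermis_z=6, dermis_hypodermis_z=16)
        bg = generate_septa_background(spec, seed=2)
        noisy = add_noise(bg, 5.0, seed=2)
        resid = noisy.data.astype(np.float64) - bg.data
        assert resid.size >= 10 ** 6
        assert np.std(resid) == pytest.approx(5.0, abs=0.1)
        assert np.mean(resid) == pytest.approx(0.0, abs=0.05)


class TestPressureGeneration:
    def test_impulse_schedule_count(self):
        spec = PhantomSpec(n_frames=36, frame_interval_min=5.0,
                           pump_start_offset_min=10.0)
        times = impulse_schedule(spec)
        assert len(times) == 34
        assert times[0] == 600.0 and times[-1] == 175 * 60.0

    def test_step_plateau_reaches_peak(self):
        spec = PhantomSpec(
            n_frames=36,
            pressure=PressureSpec(noise_sd_mbar=0.0,
                                  step_events=((20.0, 70.0, 557.0),),
                                  suppress_impulses_min=((0.0, 180.0),)))
        trace, events = generate_pressure_trace(spec, seed=0)
        assert np.max(trace.pressure_mbar) == pytest.approx(557.0)
        assert events["step_events"][0]["duration_s"] == 70 * 60.0

    def test_flat_between_impulses_without_noise(self):
        spec = PhantomSpec(n_frames=6,
                           pressure=PressureSpec(noise_sd_mbar=0.0))
        trace, _ = generate_pressure_trace(spec, seed=0)
        early = trace.pressure_mbar[trace.time_s < 9 * 60]
        assert np.ptp(early) == 0.0
        assert early[0] == spec.pressure.baseline_mbar

    def test_overlapping_steps_rejected(self):
        spec = PhantomSpec(
            n_frames=36,
            pressure=PressureSpec(step_events=((10.0, 30.0, 300.0),
                                               (20.0, 30.0, 300.0))))
        with pytest.raises(ConfigError):
            generate_pressure_trace(spec, seed=0)

    def test_saturation_clipping(self):
        spec = PhantomSpec(
            n_frames=36,
            pressure=PressureSpec(noise_sd_mbar=0.0, clip_mbar=340.0,
                                  step_events=((20.0, 70.0, 557.0),)))
        trace, _ = generate_pressure_trace(spec, seed=0)
        assert np.max(trace.pressure_mbar) == pytest.approx(340.0)


class TestSpecValidation:
    def test_intensity_ordering_enforced(self):
        with pytest.raises(ConfigError):
            PhantomSpec(depot=DepotSpec(intensity=120.0))

    def test_minimum_frames(self):
        with pytest.raises(ConfigError):
            PhantomSpec(n_frames=2)

    def test_layer_ordering(self):
        with pytest.raises(ConfigError):
            PhantomSpec(epidermis_z=30, dermis_hypodermis_z=20)
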