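"""Synthetic-data generator: closed forms, determinism, rendering, ramps."""

import numpy as np
import pandas as pd
import pytest

from envgrowth import geometry, mrebtrack, quantphase, synthgen
from envgrowth.synthgen import (
    GrowthScenario,
    MrebScenario,
    calibrate_ramp_gains,
    render_frames,
    simulate_cell_trajectory,
    simulate_mreb_tracks,
    simulate_osmotic_width_response,
)


class TestGrowthTrajectories:
    def test_noiseless_matches_closed_forms(self):
        scen = GrowthScenario(noise_cv=0.0, mass_rate=0.01, seed=1)
        tr = simulate_cell_trajectory(scen, 120.0, 1.0)
        t = tr.times_min
        assert tr.mass_pg == pytest.approx(0.5 * np.exp(0.01 * t), rel=1e-9)
        assert tr.surface_um2 == pytest.approx(19.0 * tr.mass_pg, rel=1e-9)
        L = tr.surface_um2 / (np.pi * tr.width_um)
        assert tr.length_um == pytest.approx(L, rel=1e-9)
        assert tr.volume_um3 == pytest.approx(
            geometry.spherocylinder_volume(L, tr.width_um), rel=1e-9
        )

    def test_mass_doubles_at_ln2_over_rate(self):
        scen = GrowthScenario(noise_cv=0.0, mass_rate=0.01, seed=1)
        tr = simulate_cell_trajectory(scen, 120.0, 0.1)
        m = np.interp(np.log(2) / 0.01, tr.times_min, tr.mass_pg)
        assert m == pytest.approx(1.0, rel=1e-6)  # 0.5 pg doubled

    def test_surface_to_mass_constant_through_arrest_and_shift(self):
        scen = GrowthScenario(
            noise_cv=0.0, arrest_time=30.0, shift_profile=((50.0, 0.003),), seed=2
        )
        tr = simulate_cell_trajectory(scen, 70.0, 1.0)
        keep = tr.pre_lysis()
        sm = tr.surface_to_mass[keep]
        assert np.ptp(sm) / sm[0] < 1e-9

    def test_lysis_at_programmed_surface_gain(self):
        scen = GrowthScenario(noise_cv=0.0, arrest_time=30.0,
                              lysis_surface_gain=0.20, seed=3)
        tr = simulate_cell_trajectory(scen, 120.0, 0.25)
        truth = tr.extra["truth"]
        assert tr.lysis_time is not None
        s30 = np.interp(30.0, truth.t_min, truth.surface_um2)
        s_lys = np.interp(tr.lysis_time, truth.t_min, truth.surface_um2)
        # gain reaches the target within one dt of discretisation
        assert s_lys / s30 - 1.0 == pytest.approx(0.20, abs=0.01)
        # collapse below 50% in a single frame
        k = np.searchsorted(truth.t_min.to_numpy(), tr.lysis_time)
        assert truth.mass_pg.iloc[k] / truth.mass_pg.iloc[k - 1] < 0.5

    def test_width_constant_then_widening(self):
        scen = GrowthScenario(noise_cv=0.0, arrest_time=30.0, seed=4,
                              lysis_surface_gain=10.0)
        tr = simulate_cell_trajectory(scen, 70.0, 1.0)
        w = tr.width_um
        assert np.ptp(w[tr.times_min <= 30.0]) == 0.0
        # +10% over 40 min at the default widening rate
        assert w[-1] / w[0] == pytest.approx(np.exp(0.0025 * 40.0), rel=1e-9)

    def test_seed_reproducibility(self):
        a = simulate_cell_trajectory(GrowthScenario(seed=7), 30.0, 1.0)
        b = simulate_cell_trajectory(GrowthScenario(seed=7), 30.0, 1.0)
        c = simulate_cell_trajectory(GrowthScenario(seed=8), 30.0, 1.0)
        assert np.array_equal(a.mass_pg, b.mass_pg)
        assert not np.array_equal(a.mass_pg, c.mass_pg)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_cell_trajectory(GrowthScenario(), 10.0, 10.0)
        with pytest.raises(ValueError):
            GrowthScenario(mass_rate=-0.01)
        with pytest.raises(ValueError):
            # sm_ratio so small the inferred length drops below the width
            simulate_cell_trajectory(GrowthScenario(sm_ratio=3.0, noise_cv=0.0), 10.0, 1.0)


class TestMrebTracks:
    def test_arrest_at_zero_gives_subthreshold_activity(self):
        scen = MrebScenario(arrest_time=0.0, seed=7)
        spots = simulate_mreb_tracks(scen, 10.0, 10.0)
        kept = mrebtrack.filter_tracks(spots)
        series = mrebtrack.activity(kept, 10.0, 10.0)
        assert np.all(series.activity < 0.08)

    def test_single_noiseless_track_activity_exact(self):
        scen = MrebScenario(track_speed=0.6, track_density=1e-9,
                            localization_noise=0.0, track_duration=1.0, seed=0)
        # construct one track by hand through the same machinery
        spots = pd.DataFrame(
            {"frame": np.arange(61), "t_s": np.arange(61.0),
             "x_um": 0.01 * np.arange(61), "y_um": 0.0, "track_id": 0}
        )
        series = mrebtrack.activity(mrebtrack.filter_tracks(spots), 10.0, 1.0,
                                    window_min=1.0)
        assert series.activity[0] == pytest.approx(0.06, rel=1e-9)

    def test_documented_expectation(self):
        scen = MrebScenario(track_speed=0.6, track_density=0.7, track_duration=0.5)
        assert scen.expected_activity == pytest.approx(0.21)

    def test_determinism(self):
        a = simulate_mreb_tracks(MrebScenario(seed=5), 20.0, 5.0)
        b = simulate_mreb_tracks(MrebScenario(seed=5), 20.0, 5.0)
        pd.testing.assert_frame_equal(a, b)


class TestRendering:
    def test_zero_mass_gives_blank_phase(self):
        scen = GrowthScenario(noise_cv=0.0, seed=1)
        tr = simulate_cell_trajectory(scen, 5.0, 1.0)
        tr.extra["truth"].loc[:, "mass_pg"] = 0.0
        phase, masks = render_frames(tr, pixel_size=0.05)
        assert np.all(phase == 0.0)
        assert masks.max() == 1

    def test_mass_round_trip(self):
        scen = GrowthScenario(noise_cv=0.0, seed=1)
        tr = simulate_cell_trajectory(scen, 10.0, 2.0)
        px = 0.05
        cal = quantphase.MassCalibration(pixel_area=px**2)
        phase, masks = render_frames(tr, pixel_size=px, cal=cal)
        truth = tr.extra["truth"]
        for i in range(phase.shape[0]):
            phi = quantphase.integrated_phase(phase[i], masks[i].astype(bool))
            m = quantphase.phase_to_mass(phi, cal)
            assert m == pytest.approx(truth.mass_pg.iloc[i], rel=1e-6)

    def test_mass_round_trip_with_background_noise(self):
        scen = GrowthScenario(noise_cv=0.0, seed=2)
        tr = simulate_cell_trajectory(scen, 10.0, 2.0)
        px = 0.05
        cal = quantphase.MassCalibration(pixel_area=px**2)
        phase, masks = render_frames(tr, pixel_size=px, cal=cal,
                                     background_noise=0.002)
        truth = tr.extra["truth"]
        for i in range(phase.shape[0]):
            phi = quantphase.integrated_phase(phase[i], masks[i].astype(bool))
            m = quantphase.phase_to_mass(phi, cal)
            assert m == pytest.approx(truth.mass_pg.iloc[i], rel=0.03)

    def test_mask_area_matches_projected_silhouette(self):
        scen = GrowthScenario(noise_cv=0.0, seed=1)
        tr = simulate_cell_trajectory(scen, 5.0, 1.0)
        px = 0.05
        _, masks = render_frames(tr, pixel_size=px)
        truth = tr.extra["truth"]
        area = masks[0].sum() * px**2
        want = geometry.spherocylinder_projected_area(
            truth.length_um.iloc[0], truth.width_um.iloc[0]
        )
        assert area == pytest.approx(want, rel=0.02)

    def test_oversized_cell_rejected(self):
        scen = GrowthScenario(noise_cv=0.0, seed=1)
        tr = simulate_cell_trajectory(scen, 5.0, 1.0)
        with pytest.raises(ValueError):
            render_frames(tr, pixel_size=0.05, field_shape=(10, 10))


class TestOsmoticWidth:
    def test_no_drop_no_widening(self):
        t = np.linspace(0.0, 30.0, 31)
        out = simulate_osmotic_width_response(t, np.full_like(t, 970.0), 1e-4, 1e-6)
        assert out["width_rel"].to_numpy() == pytest.approx(1.0, rel=1e-12)

    def test_step_drop_elastic_only(self):
        # sudden 520 mOsm hypo-osmotic shock: instantaneous elastic widening
        # of 2.5%, no plastic contribution
        t = np.array([0.0, 0.01, 10.0])
        osm = np.array([970.0, 450.0, 450.0])
        out = simulate_osmotic_width_response(t, osm, 0.025 / 520.0, 0.0)
        assert out["width_rel"].iloc[1] == pytest.approx(1.025, rel=1e-9)

    def test_ramp_calibrated_to_eight_percent(self):
        from envgrowth import diffusion

        setup = diffusion.PadSetup(layers=((0.1, 970.0), (0.3, 145.0)), D=1.5e-5)
        t_min = np.linspace(0.0, 30.0, 61)
        osm = diffusion.solve(setup, t_min * 60.0, [0.0]).concentration[:, 0]
        e_gain, p_rate = calibrate_ramp_gains(t_min, osm)
        out = simulate_osmotic_width_response(t_min, osm, e_gain, p_rate)
        w20 = np.interp(20.0, out["t_min"], out["width_rel"])
        assert w20 - 1.0 == pytest.approx(0.08, abs=1e-9)

    def test_rising_osmolality_rejected(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_osmotic_width_response(t, np.array([500.0, 600.0, 700.0]), 0, 0)
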