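"""Synthetic-data generators: determinism, structure and round trips."""

import numpy as np
import pandas as pd
import pytest

from cavistress import fitting, hydraulics, synthesis
from cavistress.synthesis import ORDER_LABELS


class TestGeometry:
    def test_deterministic_under_seed(self):
        a = synthesis.build_leaf_geometry(seed=5)
        b = synthesis.build_leaf_geometry(seed=5)
        assert np.array_equal(a.order_mask, b.order_mask)
        assert np.array_equal(a.segment_map, b.segment_map)
        assert a.segments.equals(b.segments)

    def test_minimum_composition(self, geometry):
        by = geometry.segments.groupby("order").size()
        assert by["midrib"] >= 1
        assert by["major"] >= 6
        assert by["hov"] >= 50

    def test_served_areas_tile_mesophyll(self, geometry):
        hov_ids = geometry.segments.loc[
            geometry.segments["order"] == "hov", "segment_id"
        ]
        total = sum(geometry.served_area_px(int(s)) for s in hov_ids)
        assert abs(total - geometry.mesophyll_area_px) <= 0.01 * geometry.mesophyll_area_px

    def test_pixel_count_ordering(self, geometry):
        om = geometry.order_mask
        n = {k: int((om == v).sum()) for k, v in ORDER_LABELS.items()}
        assert n["hov"] > n["major"] > n["midrib"] > 0

    def test_each_vein_pixel_has_one_label_and_segment(self, geometry):
        vein = geometry.segment_map > 0
        labs = geometry.order_mask[vein]
        assert np.all(np.isin(labs, [1, 2, 3]))

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            synthesis.GeometryConfig(hov_spacing_px=1)
        with pytest.raises(ValueError):
            synthesis.GeometryConfig(pixel_scale_um=60.0)


class TestPsychrometer:
    def test_noiseless_exact_line(self):
        s = synthesis.generate_psychrometer_series(noise_sd=0.0)
        slope = np.diff(s["psi_stem_mpa"]).mean() / 5.0
        assert slope == pytest.approx((-6.0 + 0.5) / (5 * 1440), rel=1e-9)
        assert s["psi_stem_mpa"].iloc[0] == pytest.approx(-0.5)

    def test_seeded_noise_reproducible(self):
        a = synthesis.generate_psychrometer_series(noise_sd=0.05, seed=3)
        b = synthesis.generate_psychrometer_series(noise_sd=0.05, seed=3)
        assert a.equals(b)

    def test_replicate_mean_converges_to_midpoint(self):
        rng = np.random.default_rng(0)
        mids = [
            synthesis.generate_psychrometer_series(
                days=1, noise_sd=0.2, seed=rng
            )["psi_stem_mpa"].iloc[144]
            for _ in range(100)
        ]
        expected = -0.5 + (-5.5) * 720 / 1440.0
        assert np.mean(mids) == pytest.approx(expected, abs=3 * 0.2 / 10)

    def test_inverted_ramp_rejected(self):
        with pytest.raises(ValueError):
            synthesis.generate_psychrometer_series(psi0=-6, psi_end=-0.5)


class TestEventSchedule:
    def test_hov_cavitate_exactly_once(self, geometry, full_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, full_psi_series, seed=11)
        hov = sch.events[sch.events["order"] == "hov"]
        counts = hov.groupby("segment_id").size()
        assert (counts <= 1).all()

    def test_deterministic_under_seed(self, geometry, full_psi_series):
        a = synthesis.schedule_cavitation_events(geometry, full_psi_series, seed=4)
        b = synthesis.schedule_cavitation_events(geometry, full_psi_series, seed=4)
        assert a.events.equals(b.events)

    def test_hov_median_trigger_near_p50(self, geometry, full_psi_series):
        # pooled across several replicates, the 50% crossing of the HOV
        # schedule approaches the configured p50 of -4.07
        rng = np.random.default_rng(21)
        trig = []
        for _ in range(6):
            sch = synthesis.schedule_cavitation_events(
                geometry, full_psi_series, seed=rng
            )
            trig.extend(
                sch.events.loc[sch.events["order"] == "hov", "psi_trigger_mpa"]
            )
        assert np.median(trig) == pytest.approx(-4.07, abs=0.1)

    def test_larger_orders_receive_configured_mean_counts(
        self, geometry, full_psi_series
    ):
        rng = np.random.default_rng(13)
        mids, majs = [], []
        for _ in range(8):
            sch = synthesis.schedule_cavitation_events(
                geometry, full_psi_series, seed=rng
            )
            per = sch.events.groupby(["order", "segment_id"]).size()
            mids.append(per["midrib"].mean())
            majs.append(per["major"].mean())
        assert np.mean(mids) == pytest.approx(9.4, abs=0.4)
        assert np.mean(majs) == pytest.approx(4.53, abs=0.25)

    def test_truncation_warns(self, geometry):
        shallow = synthesis.generate_psychrometer_series(
            psi0=-0.5, psi_end=-3.0, days=1, seed=0
        )
        with pytest.warns(UserWarning, match="truncated"):
            synthesis.schedule_cavitation_events(geometry, shallow, seed=0)


class TestRenderStack:
    def test_noiseless_events_give_exact_difference_episodes(
        self, geometry, short_psi_series
    ):
        sch = synthesis.schedule_cavitation_events(geometry, short_psi_series, seed=1)
        # three events at well-separated frames (coincident flashes would
        # share difference episodes)
        ev_sorted = sch.events.sort_values("frame")
        keep, last = [], -10
        for _, r in ev_sorted.iterrows():
            if r["frame"] - last >= 5:
                keep.append(r)
                last = r["frame"]
            if len(keep) == 3:
                break
        sub = pd.DataFrame(keep)
        small = synthesis.EventSchedule(
            events=sub.reset_index(drop=True),
            footprints={int(e): sch.footprints[int(e)] for e in sub["event_id"]},
            n_frames=sch.n_frames,
        )
        cfg = synthesis.RenderConfig(noise_sd=0.0)
        stack = synthesis.render_stack(geometry, small, config=cfg, seed=0)
        diff = np.abs(np.diff(stack, axis=0))
        frames_hit = np.nonzero(diff.max(axis=(1, 2)) > 0)[0]
        # each flash: one onset and one offset episode
        assert len(frames_hit) == 2 * len(sub)

    def test_flash_snr_at_default_config(self):
        cfg = synthesis.RenderConfig()
        assert cfg.flash_amplitude / cfg.noise_sd >= 5.0

    def test_shrink_disabled_width_constant(self, geometry, short_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, short_psi_series, seed=1)
        cfg = synthesis.RenderConfig(noise_sd=0.0, shrink=False)
        stack = synthesis.render_stack(geometry, sch, config=cfg, seed=0)
        # margin row content identical in first and last frames
        assert np.array_equal(stack[0] > 100, stack[-1] > 100)

    def test_deterministic_under_seed(self, geometry, short_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, short_psi_series, seed=1)
        a = synthesis.render_stack(geometry, sch, seed=9)
        b = synthesis.render_stack(geometry, sch, seed=9)
        assert np.array_equal(a, b)


class TestScalarSeries:
    def test_width_inverts_printed_calibration(self):
        w = synthesis.generate_width_series(np.array([-1.0038]))
        assert w[0] == pytest.approx(100.0, abs=0.01)
        assert synthesis.generate_width_series(np.array([0.0]))[0] == pytest.approx(106.22)

    def test_width_slope_recovered_by_ols(self):
        psi = np.linspace(-0.5, -4.4, 30)
        w = synthesis.generate_width_series(psi)
        fit = fitting.fit_linear(psi, w)
        assert fit.slope == pytest.approx(6.1963, abs=1e-9)
        assert fit.intercept == pytest.approx(106.22, abs=1e-9)

    def test_piecewise_leaf_potential_decouples(self):
        ps = np.linspace(-0.5, -6.0, 100)
        pl = synthesis.piecewise_psi_leaf(ps, -3.62, 3.0)
        assert np.allclose(pl[ps >= -3.62], ps[ps >= -3.62])
        assert pl[-1] == pytest.approx(-3.62 + 3.0 * (-6.0 + 3.62))

    def test_fvfm_plateau_and_death(self):
        psi = np.linspace(-0.5, -6.0, 200)
        fv = synthesis.generate_fvfm_series(psi)
        assert fv[psi >= -3.53].max() == pytest.approx(0.80)
        assert fv[psi >= -3.53].min() == pytest.approx(0.80)
        assert fv[-1] < 0.2  # dead below the fluorescence threshold

    def test_fvfm_control_mode_flat(self):
        psi = np.full(100, -0.6)
        fv = synthesis.generate_fvfm_series(psi, breakpoint_mpa=-3.53)
        assert np.ptp(fv) == 0.0


class TestGminTrace:
    def test_round_trip_recovery(self):
        tr = synthesis.generate_gmin_trace(gmin=10.02, seed=2)
        g, _ = fitting.gmin_from_trace(
            tr["time_s"], tr["mass_g"], 1.5e-3, 24.31, 35.86
        )
        assert g == pytest.approx(10.02, rel=0.02)

    def test_zero_vpd_flat_trace(self):
        env = hydraulics.Environment(temp_c=20.0, rh_pct=100.0, gmin=10.0)
        tr = synthesis.generate_gmin_trace(gmin=10.0, env=env)
        assert np.ptp(tr["mass_g"]) == pytest.approx(0.0, abs=1e-12)

    def test_stomatal_phase_precedes_linear_phase(self):
        tr = synthesis.generate_gmin_trace(gmin=10.0, stomatal_minutes=60, seed=0)
        t, m = tr["time_s"].to_numpy(), tr["mass_g"].to_numpy()
        early = (m[0] - m[10]) / (t[10] - t[0])
        late = (m[-11] - m[-1]) / (t[-1] - t[-11])
        assert early > 1.5 * late


class TestPvSeries:
    def test_round_trip_recovery(self):
        pv = synthesis.generate_pv_series(tlp=-2.01, n_points=20, seed=3)
        res = fitting.tlp_from_pv(pv["psi_mpa"], pv["mass_g"], 2.0)
        assert res["tlp"] == pytest.approx(-2.01, abs=0.05)

    def test_mass_monotone_decline(self):
        pv = synthesis.generate_pv_series()
        assert (np.diff(pv["mass_g"]) < 0).all()

    def test_terminal_slope_matches_osmotic_parameter(self):
        pv = synthesis.generate_pv_series(
            osmotic_ft=-1.7, apoplastic_fraction=0.3, water_fraction=0.7
        )
        res = fitting.tlp_from_pv(pv["psi_mpa"], pv["mass_g"], 2.0)
        expected = 1.0 / (0.7 * 1.7) / 0.7  # d(1/psi)/d(deficit of sat. mass)
        assert res["slope"] == pytest.approx(expected, rel=0.02)
        assert res["osmotic_potential_ft"] == pytest.approx(-1.7, abs=0.05)


class TestRehydration:
    def test_round_trip_recovers_kmax(self):
        rec = synthesis.generate_rehydration_samples(seed=0)
        ks = [
            fitting.kleaf_instance(
                r.fmax, r.f2, r.psi_init_mpa, r.psi_fin_mpa, r.area_m2, r.temp_c
            ).k_mean
            for r in rec.itertuples()
        ]
        fit = fitting.fit_kleaf_curve(rec["psi_init_mpa"], ks)
        assert fit.kmax == pytest.approx(5.77, abs=1e-3)

    def test_zero_initial_potential_guarded(self):
        with pytest.raises(ValueError):
            fitting.kleaf_instance(1.0, 0.5, 0.0, -1.0, 1.0)

    def test_injected_disagreement_flagged(self):
        rec = synthesis.generate_rehydration_samples(seed=0).iloc[2]
        inst = fitting.kleaf_instance(
            rec.fmax * 1.2, rec.f2, rec.psi_init_mpa, rec.psi_fin_mpa,
            rec.area_m2, rec.temp_c,
        )
        assert inst.flagged
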