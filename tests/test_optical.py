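"""Difference imaging, event detection, order assignment and derived maps."""

import numpy as np
import pandas as pd
import pytest

from cavistress import optical, synthesis
from cavistress.optical import CavitationEvent


def _flash(stack, frame, rows, cols, amp=10.0, frames=2):
    stack[frame: frame + frames, rows[0]: rows[1], cols[0]: cols[1]] += amp


class TestDifferenceStack:
    def test_constant_stack_all_zero(self):
        d = optical.difference_stack(np.full((5, 8, 8), 7.0))
        assert d.shape == (4, 8, 8)
        assert not d.any()

    def test_single_flash_episodes(self):
        stack = np.zeros((10, 16, 16), np.float32)
        _flash(stack, 4, (5, 8), (5, 9), amp=3.0, frames=2)
        d = optical.difference_stack(stack)
        hot = np.nonzero(d.max(axis=(1, 2)))[0]
        assert list(hot) == [3, 5]          # onset and offset
        assert d[3].max() == pytest.approx(3.0)

    def test_difference_of_linear_ramp_constant(self):
        t = np.arange(12, dtype=np.float32)
        stack = np.ones((12, 4, 4), np.float32) * t[:, None, None] * 2.5
        d = optical.difference_stack(stack)
        assert np.allclose(d, 2.5)

    def test_short_stack_rejected(self):
        with pytest.raises(ValueError):
            optical.difference_stack(np.zeros((1, 4, 4)))


class TestDetectEvents:
    def test_planted_flashes_recall_and_precision(self):
        rng = np.random.default_rng(0)
        n_frames, H, W = 120, 128, 128
        stack = rng.normal(0, 2.0, (n_frames, H, W)).astype(np.float32) + 100
        truth = []
        for k in range(25):
            f = 4 + 4 * k
            # spatially disjoint plants: coincident overlapping flashes
            # would be one physical event
            while True:
                r = int(rng.integers(4, H - 10))
                c = int(rng.integers(4, W - 10))
                if all(abs(r - r0) > 8 or abs(c - c0) > 10 for _, r0, c0 in truth):
                    break
            _flash(stack, f, (r, r + 4), (c, c + 6), amp=10.0, frames=2)
            truth.append((f, r, c))
        events = optical.detect_events(optical.difference_stack(stack))
        # recall: every planted flash matched at the right onset frame
        matched = 0
        for f, r, c in truth:
            ok = [
                e for e in events
                if abs(e.start_frame - (f - 1)) <= 1
                and abs(e.centroid[0] - (r + 1.5)) < 4
                and abs(e.centroid[1] - (c + 2.5)) < 4
            ]
            matched += bool(ok)
        recall = matched / 25
        precision = matched / max(len(events), 1)
        assert recall >= 0.98
        assert precision >= 0.98

    def test_noise_only_stack_yields_nothing(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(0, 2.0, (60, 96, 96)).astype(np.float32)
        assert optical.detect_events(optical.difference_stack(stack)) == []

    def test_overlapping_flashes_merge_within_window(self):
        stack = np.zeros((12, 24, 24), np.float32)
        stack[4, 8:12, 8:14] = 10.0
        stack[5, 8:12, 10:16] = 10.0
        d = optical.difference_stack(stack)
        events = optical.detect_events(d, threshold=5.0, merge_window=2,
                                       min_span_frames=1)
        assert len(events) == 1

    def test_empty_stack_gives_empty_list(self):
        assert optical.detect_events(np.zeros((0, 4, 4))) == []

    def test_unknown_threshold_rule_rejected(self):
        with pytest.raises(ValueError):
            optical.detect_events(np.ones((3, 4, 4)), threshold="median")

    def test_deterministic_and_invariant_to_zero_frame(self):
        rng = np.random.default_rng(1)
        stack = rng.normal(0, 2.0, (30, 64, 64)).astype(np.float32)
        _flash(stack, 10, (20, 24), (20, 26))
        d = optical.difference_stack(stack)
        e1 = optical.detect_events(d)
        e2 = optical.detect_events(d)
        padded = np.concatenate([d, np.zeros((1, 64, 64), np.float32)])
        e3 = optical.detect_events(padded)
        sig = lambda evs: [(e.start_frame, e.area_px) for e in evs]
        assert sig(e1) == sig(e2) == sig(e3)


class TestAssignOrder:
    def test_majority_and_tiebreak(self, geometry):
        om, sm = geometry.order_mask, geometry.segment_map
        hov_r, hov_c = np.nonzero(om == 3)
        ev = CavitationEvent(1, 0, 1, hov_r[:10], hov_c[:10], 10,
                             (float(hov_r[:10].mean()), float(hov_c[:10].mean())))
        out = optical.assign_vein_order([ev], om, sm)
        assert out[0].order == "hov"

        # 60/40 midrib/major majority -> midrib
        mid_r, mid_c = np.nonzero(om == 1)
        maj_r, maj_c = np.nonzero(om == 2)
        rows = np.concatenate([mid_r[:6], maj_r[:4]])
        cols = np.concatenate([mid_c[:6], maj_c[:4]])
        ev = CavitationEvent(2, 0, 1, rows, cols, 10,
                             (float(mid_r[:6].mean()), float(mid_c[:6].mean())))
        assert optical.assign_vein_order([ev], om, sm)[0].order == "midrib"

        # exact tie -> lower order wins
        rows = np.concatenate([mid_r[:5], maj_r[:5]])
        cols = np.concatenate([mid_c[:5], maj_c[:5]])
        ev = CavitationEvent(3, 0, 1, rows, cols, 10,
                             (float(mid_r[:5].mean()), float(mid_c[:5].mean())))
        assert optical.assign_vein_order([ev], om, sm)[0].order == "midrib"

    def test_background_event_excluded_with_warning(self, geometry):
        ev = CavitationEvent(1, 0, 1, np.array([0, 0]), np.array([0, 1]), 2,
                             (0.0, 0.5))
        with pytest.warns(UserWarning, match="background"):
            out = optical.assign_vein_order(
                [ev], geometry.order_mask, geometry.segment_map
            )
        assert out == []

    def test_rendered_round_trip_order_accuracy(self, geometry):
        # two-day ramp: enough frames that distinct events rarely coincide
        psi = synthesis.generate_psychrometer_series(days=2.0, seed=0)
        sch = synthesis.schedule_cavitation_events(geometry, psi, seed=6)
        stack = synthesis.render_stack(geometry, sch, seed=7)
        events = optical.detect_events(optical.difference_stack(stack))
        events = optical.assign_vein_order(
            events, geometry.order_mask, geometry.segment_map
        )
        # match detections to ground truth by pixel-and-frame overlap
        gt = [
            (int(r["frame"]), r["order"],
             set(zip(*sch.footprints[int(r["event_id"])])))
            for _, r in sch.events.iterrows()
        ]
        checked = wrong = 0
        for e in events:
            pix = set(zip(e.rows.tolist(), e.cols.tolist()))
            hits = [
                o for f, o, fp in gt
                if abs(f - 1 - e.start_frame) <= 2 and len(pix & fp) > 0
            ]
            if not hits:
                continue
            checked += 1
            wrong += e.order not in hits
        assert checked >= 0.9 * len(sch.events)
        assert wrong == 0


class TestCumulativeCurves:
    def test_single_event_steps_to_one(self):
        ev = CavitationEvent(1, 3, 4, np.arange(5), np.arange(5), 5, (2, 2),
                             order="hov", segment_id=1, psi_stem_mpa=-2.5)
        curves = optical.cumulative_cavitation([ev])
        c = curves["hov"]
        assert len(c) == 1
        assert c["cum_area_frac"].iloc[0] == 1.0
        assert c["psi_stem_mpa"].iloc[0] == -2.5

    def test_curve_is_cdf_like_and_crossing_matches_p50(self):
        rng = np.random.default_rng(5)
        n = 400
        u = rng.uniform(0, 1, n)
        psi = -3.73 + 0.25 * np.log((1 - u) / u)
        events = [
            CavitationEvent(i, i, i, np.arange(4), np.arange(4), 4, (0, 0),
                            order="hov", segment_id=1, psi_stem_mpa=float(p))
            for i, p in enumerate(psi)
        ]
        c = optical.cumulative_cavitation(events)["hov"]
        assert (np.diff(c["cum_area_frac"]) >= -1e-12).all()
        assert c["cum_area_frac"].iloc[-1] == pytest.approx(1.0)
        assert optical.crossing_psi(c, 0.5) == pytest.approx(-3.73, abs=0.1)

    def test_event_order_permutation_invariance(self):
        rng = np.random.default_rng(8)
        psi = rng.uniform(-5, -1, 40)
        def build(perm):
            return [
                CavitationEvent(i, i, i, np.arange(3), np.arange(3), 3, (0, 0),
                                order="major", segment_id=1,
                                psi_stem_mpa=float(psi[j]))
                for i, j in enumerate(perm)
            ]
        c1 = optical.cumulative_cavitation(build(np.arange(40)))["major"]
        c2 = optical.cumulative_cavitation(build(rng.permutation(40)))["major"]
        assert np.allclose(c1["psi_stem_mpa"], c2["psi_stem_mpa"])
        assert np.allclose(c1["cum_area_frac"], c2["cum_area_frac"])

    def test_join_requires_series_coverage(self, short_psi_series):
        ev = CavitationEvent(1, 10_000, 10_000, np.arange(3), np.arange(3), 3,
                             (0, 0), order="hov", segment_id=1)
        with pytest.raises(ValueError, match="outside"):
            optical.join_psi([ev], short_psi_series)


class TestEventsPerSegment:
    def test_empty_event_list_gives_zeros(self, geometry):
        out = optical.events_per_segment([], geometry.segments)
        assert (out["mean"] == 0).all()

    def test_counts_distinct_events(self, geometry):
        sid = int(geometry.segments.loc[
            geometry.segments["order"] == "midrib", "segment_id"
        ].iloc[0])
        events = [
            CavitationEvent(i, i, i, np.arange(3), np.arange(3), 3, (0, 0),
                            order="midrib", segment_id=sid)
            for i in range(3)
        ]
        out = optical.events_per_segment(events, geometry.segments)
        mid = out[out["order"] == "midrib"].iloc[0]
        n_mid = (geometry.segments["order"] == "midrib").sum()
        assert mid["mean"] == pytest.approx(3.0 / n_mid)


class TestLeafWidth:
    def test_shrink_disabled_constant(self, geometry, short_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, short_psi_series, seed=2)
        cfg = synthesis.RenderConfig(noise_sd=0.0, shrink=False)
        stack = synthesis.render_stack(geometry, sch, config=cfg, seed=0)
        w = optical.measure_leaf_width(stack, geometry.midrib_row)
        assert np.allclose(w["width_pct"], 100.0)

    def test_round_trip_within_one_pixel(self, geometry, short_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, short_psi_series, seed=2)
        n = sch.n_frames
        wpct = np.linspace(100.0, 88.0, n)
        cfg = synthesis.RenderConfig(noise_sd=0.5, shrink=True)
        stack = synthesis.render_stack(geometry, sch, width_pct=wpct,
                                       config=cfg, seed=1)
        w = optical.measure_leaf_width(stack, geometry.midrib_row)
        target_px = geometry.half_width_px * wpct / 100.0
        assert np.nanmax(np.abs(w["width_px"] - target_px)) <= 1.0


class TestFunctionalArea:
    @staticmethod
    def _hov_events(geometry, schedule):
        events = []
        hov = schedule.events[schedule.events["order"] == "hov"]
        for k, (_, ev) in enumerate(hov.iterrows(), start=1):
            rr, cc = schedule.footprints[int(ev["event_id"])]
            events.append(CavitationEvent(
                k, int(ev["frame"]), int(ev["frame"]), rr, cc, int(rr.size),
                (float(rr.mean()), float(cc.mean())), order="hov",
                segment_id=int(ev["segment_id"]),
                psi_stem_mpa=float(ev["psi_trigger_mpa"]),
            ))
        return events

    def test_no_events_full_area(self, geometry):
        fa = optical.functional_area_remaining([], geometry)
        assert fa["pct_remaining"].iloc[0] == 100.0

    def test_all_hov_cavitated_leaves_only_large_vein_residual(
        self, geometry, full_psi_series
    ):
        sch = synthesis.schedule_cavitation_events(geometry, full_psi_series, seed=3)
        events = self._hov_events(geometry, sch)
        fa = optical.functional_area_remaining(events, geometry)
        assert fa["pct_remaining"].iloc[-1] <= 5.0
        assert (np.diff(fa["pct_remaining"]) <= 1e-9).all()

    def test_single_event_subtracts_its_served_share(self, geometry):
        sid = int(geometry.segments.loc[
            geometry.segments["order"] == "hov", "segment_id"
        ].iloc[0])
        rr, cc = geometry.segment_pixels(sid)
        ev = CavitationEvent(1, 0, 1, rr, cc, rr.size,
                             (float(rr.mean()), float(cc.mean())),
                             order="hov", segment_id=sid, psi_stem_mpa=-3.0)
        fa = optical.functional_area_remaining([ev], geometry)
        share = 100.0 * geometry.served_area_px(sid) / geometry.lamina_area_px
        assert fa["pct_remaining"].iloc[-1] == pytest.approx(100.0 - share)

    def test_commutes_with_event_reordering(self, geometry, full_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, full_psi_series, seed=5)
        events = self._hov_events(geometry, sch)[:20]
        fa1 = optical.functional_area_remaining(events, geometry)
        fa2 = optical.functional_area_remaining(events[::-1], geometry)
        assert fa1["pct_remaining"].iloc[-1] == pytest.approx(
            fa2["pct_remaining"].iloc[-1]
        )

    def test_brush_mode_also_monotone(self, geometry, full_psi_series):
        sch = synthesis.schedule_cavitation_events(geometry, full_psi_series, seed=5)
        events = self._hov_events(geometry, sch)[:10]
        fb = optical.functional_area_remaining(events, geometry, mode="brush")
        assert (np.diff(fb["pct_remaining"]) <= 1e-9).all()
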