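"""Dwell-event detection, survival curves, biexponential fits, heat maps."""

import numpy as np
import pytest

from divtrack.dwell import (
    confinement_heatmap,
    detect_dwell_events,
    dwell_survival,
    fit_survival_biexponential,
)
from divtrack.geometry import CellGeometry
from divtrack.simulate import SimConfig, simulate_dwell_durations, simulate_tracks
from divtrack.tracks import TrackSet

from conftest import make_track


def _ts(tracks, dt=0.024):
    return TrackSet(tracks=tracks, frame_interval=dt)


class TestDetection:
    def test_stationary_track_one_censored_event(self):
        ts = _ts([make_track(0, np.zeros((10, 2)))])
        events = detect_dwell_events(ts)
        assert len(events) == 1
        assert events[0].n_frames == 10 and events[0].censored

    def test_large_steps_no_events(self):
        xy = np.column_stack([np.arange(10) * 0.2, np.zeros(10)])  # 200 nm steps
        events = detect_dwell_events(_ts([make_track(0, xy)]), min_event_frames=3)
        assert events == []

    def test_immobile_then_mobile_exact_length(self):
        xy = np.vstack([np.zeros((8, 2)),
                        np.column_stack([np.arange(1, 5), np.zeros(4)])])
        events = detect_dwell_events(_ts([make_track(0, xy)]))
        assert len(events) == 1
        assert events[0].n_frames == 8 and not events[0].censored

    def test_each_localization_in_at_most_one_event(self):
        cfg = SimConfig(components=[(0.005, 0.7), (0.3, 0.3)], frame_interval=0.024,
                        n_tracks=100, seed=3)
        ts = simulate_tracks(cfg)
        events = detect_dwell_events(ts, min_event_frames=1)
        for tid in {e.track_id for e in events}:
            evs = sorted(
                (e for e in events if e.track_id == tid), key=lambda e: e.start_frame
            )
            for a, b in zip(evs, evs[1:]):
                assert a.start_frame + a.n_frames <= b.start_frame

    def test_smaller_radius_never_lengthens_events(self):
        cfg = SimConfig(components=[(0.01, 1.0)], frame_interval=0.024,
                        n_tracks=30, seed=4)
        ts = simulate_tracks(cfg)
        for tight, loose in [(0.05, 0.097), (0.097, 0.2)]:
            d_tight = sum(e.n_frames for e in detect_dwell_events(ts, radius=tight))
            d_loose = sum(e.n_frames for e in detect_dwell_events(ts, radius=loose))
            assert d_tight <= d_loose

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            detect_dwell_events(_ts([make_track(0, np.zeros((5, 2)))]), radius=0)


class TestSurvival:
    def test_counting(self):
        curve = dwell_survival([1.0, 2.0, 3.0], frame_interval=1.0, min_events=1)
        assert np.allclose(curve.survival, [1.0, 2 / 3, 1 / 3])

    def test_monotone_non_increasing(self):
        d = simulate_dwell_durations(0.4, 0.1, 0.5, 5000, 0.024, seed=5)
        curve = dwell_survival(d, frame_interval=0.024)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival[0] == 1.0

    def test_exponential_supnorm_oracle(self):
        """Discretization-corrected survival matches exp(−t/τ) within 0.01."""
        tau, dt = 0.2, 0.024
        d = simulate_dwell_durations(1.0, tau, tau, 100000, dt, seed=6)
        curve = dwell_survival(d, frame_interval=dt)
        # duration k·dt means the underlying time exceeded (k−1)·dt
        expected = np.exp(-(curve.times - dt) / tau)
        assert np.abs(curve.survival - expected).max() < 0.01

    def test_no_events_error(self):
        with pytest.raises(ValueError):
            dwell_survival([], frame_interval=0.024)


class TestBiexponentialFit:
    def test_single_exponential_degenerates(self):
        d = simulate_dwell_durations(1.0, 0.2, 0.2, 20000, 0.024, seed=7)
        fit = fit_survival_biexponential(dwell_survival(d, 0.024), seed=7)
        collapsed = fit.tau2 / fit.tau1 < 1.5
        vanishing = min(fit.p1, fit.p2) < 0.05
        assert collapsed or vanishing
        # either way the dominant time constant is right
        dominant = fit.tau1 if fit.p1 >= fit.p2 else fit.tau2
        assert dominant == pytest.approx(0.2, rel=0.1)

    def test_cgb_wildtype_row_recovery(self):
        """Long component of the 24 ms dwell mixture within 10% / 5 points."""
        d = simulate_dwell_durations(0.347, 0.19, 0.76, 10000, 0.024, seed=8)
        fit = fit_survival_biexponential(dwell_survival(d, 0.024), seed=8)
        assert fit.tau2 == pytest.approx(0.76, rel=0.10)
        assert abs(fit.p2 * 100 - 65.3) <= 5.0

    def test_bsu_wildtype_row_recovery(self):
        """Long component of the 9 ms dwell mixture within 15%."""
        d = simulate_dwell_durations(0.193, 0.036, 0.11, 10000, 0.009, seed=9)
        fit = fit_survival_biexponential(dwell_survival(d, 0.009), seed=9)
        assert fit.tau2 == pytest.approx(0.11, rel=0.15)

    def test_roundtrip_self_consistency(self):
        """Re-simulating from the fit and re-fitting recovers the fit."""
        p1, t1, t2, dt = 0.4, 0.15, 0.8, 0.024
        d = simulate_dwell_durations(p1, t1, t2, 20000, dt, seed=10)
        fit1 = fit_survival_biexponential(dwell_survival(d, dt), seed=10)
        d2 = simulate_dwell_durations(fit1.p1, fit1.tau1, fit1.tau2, 20000, dt, seed=11)
        fit2 = fit_survival_biexponential(dwell_survival(d2, dt), seed=11)
        assert fit2.tau2 == pytest.approx(fit1.tau2, rel=0.1)
        assert abs(fit2.p2 - fit1.p2) < 0.05

    def test_short_curve_rejected(self):
        curve = dwell_survival([1.0, 2.0, 3.0], frame_interval=1.0, min_events=1)
        with pytest.raises(ValueError):
            fit_survival_biexponential(curve)


class TestHeatmap:
    def _labeled_ts(self, geo, n=300, seed=12):
        cfg = SimConfig(components=[(0.02, 1.0)], frame_interval=0.024,
                        n_tracks=n, seed=seed, geometry=geo, loc_error_sd=0.0)
        ts = simulate_tracks(cfg)
        for tr in ts.tracks:
            tr.motion_label = "confined"
        return ts

    def test_counts_conserved_and_symmetric(self):
        geo = CellGeometry.rod(3.0, 1.0)
        ts = self._labeled_ts(geo)
        cmap = confinement_heatmap(ts, geo)
        assert cmap.counts.sum() == pytest.approx(cmap.n_points)
        assert np.allclose(cmap.counts, cmap.counts[:, ::-1])

    def test_uniform_points_near_uniform_density(self):
        # sphere avoids the rod's pole-area bias; interior bins only
        geo = CellGeometry.sphere(2.0)
        rng = np.random.default_rng(13)
        pts = geo.sample_uniform(200000, rng)
        ts = TrackSet(
            tracks=[make_track(0, pts)], frame_interval=0.024
        )
        ts.tracks[0].frames = np.arange(len(pts))
        ts.tracks[0].motion_label = "confined"
        cmap = confinement_heatmap(ts, geo, bins=(10, 10), smooth_sigma_bins=0.0)
        # expected count per bin from the circle's chord geometry
        xe, ye = cmap.x_edges, cmap.y_edges
        exp = np.zeros_like(cmap.counts)
        from scipy import integrate
        for i in range(len(xe) - 1):
            for j in range(len(ye) - 1):
                area, _ = integrate.dblquad(
                    lambda y, x: (x * x + y * y <= 1.0) * 1.0,
                    xe[i], xe[i + 1], ye[j], ye[j + 1]
                )
                exp[i, j] = area
        exp *= cmap.n_points / exp.sum()
        interior = exp > 0.9 * exp.max()
        rel = np.abs(cmap.counts[interior] - exp[interior]) / exp[interior]
        assert rel.max() < 0.10

    def test_empty_warns(self):
        geo = CellGeometry.rod(3.0, 1.0)
        ts = TrackSet(tracks=[make_track(0, np.zeros((5, 2)))], frame_interval=0.024)
        with pytest.warns(UserWarning):
            cmap = confinement_heatmap(ts, geo)
        assert cmap.n_points == 0
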