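"""MSD and squared-displacement statistics, mixture fitting, classification."""

import numpy as np
import pytest
from scipy import optimize

from divtrack.diffusion import (
    MSDCurve,
    classify_tracks,
    compute_ensemble_msd,
    compute_squared_displacements,
    fit_msd_linear,
    fit_sqd_mixture_global,
)
from divtrack.simulate import SimConfig, draw_squared_displacements, simulate_tracks
from divtrack.tracks import TrackSet

from conftest import make_track


class TestSquaredDisplacements:
    def test_three_four_five_step(self, simple_trackset):
        # track 0: (0,0)->(0.3,0.4) is 0.5 µm, the trailing point is dropped
        sq = compute_squared_displacements(
            TrackSet(tracks=[simple_trackset.tracks[0]], frame_interval=0.024)
        )
        assert sq == pytest.approx([0.25])

    def test_gap_pairs_excluded(self, simple_trackset):
        # track 2 frames [0,1,4]: after dropping the last point only (0,1) remains
        sq = compute_squared_displacements(
            TrackSet(tracks=[simple_trackset.tracks[2]], frame_interval=0.024)
        )
        assert len(sq) == 1 and sq[0] == pytest.approx(0.01)

    def test_mean_sqd_matches_4Ddt(self):
        D, dt = 0.05, 0.024
        ts = simulate_tracks(
            SimConfig(components=[(D, 1.0)], frame_interval=dt, n_tracks=3000,
                      loc_error_sd=0.0, seed=21)
        )
        sq = compute_squared_displacements(ts)
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * D * dt) < 3 * se

    def test_lag_validation(self, simple_trackset):
        with pytest.raises(ValueError):
            compute_squared_displacements(simple_trackset, lag_frames=0)


class TestEnsembleMSD:
    def test_stationary_tracks_zero(self):
        ts = TrackSet(tracks=[make_track(0, np.zeros((10, 2)))], frame_interval=0.024)
        curve = compute_ensemble_msd(ts)
        assert np.allclose(curve.msd, 0)

    def test_ballistic_drift_closed_form(self):
        v, dt = 1.0, 0.024
        t = np.arange(30) * dt
        ts = TrackSet(
            tracks=[make_track(0, np.column_stack([v * t, np.zeros(30)]))],
            frame_interval=dt,
        )
        curve = compute_ensemble_msd(ts, n_lags=4)
        assert np.allclose(curve.msd, (v * curve.lags) ** 2, rtol=1e-12)


class TestMSDFit:
    def test_exact_line_recovered(self):
        lags = np.array([0.024, 0.048, 0.072, 0.096])
        curve = MSDCurve(lags=lags, msd=4 * 0.1 * lags + 0.002,
                         n_pairs=np.ones(4, dtype=int))
        fit = fit_msd_linear(curve)
        assert fit.D == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(0.002, abs=1e-12)

    def test_insufficient_lags(self):
        curve = MSDCurve(lags=[0.024], msd=[0.01], n_pairs=[5])
        with pytest.raises(ValueError):
            fit_msd_linear(curve)


class TestSQDMixture:
    def test_single_component_matches_closed_form(self):
        """One-component fit equals an independent 1-parameter CDF fit."""
        dt = 0.024
        sqd = draw_squared_displacements([(0.05, 1.0)], 20000, dt, seed=3)
        mix = fit_sqd_mixture_global({"c": sqd}, n_components=1, frame_interval=dt)

        # independent oracle: scalar least squares on the same Hazen ECDF
        u = np.sort(sqd)
        probs = (np.arange(len(u)) + 0.5) / len(u)
        idx = np.unique(np.linspace(0, len(u) - 1, 2000).round().astype(int))
        u, probs = u[idx], probs[idx]
        res = optimize.minimize_scalar(
            lambda logD: np.sum(
                (1 - np.exp(-u / (4 * 10.0**logD * dt)) - probs) ** 2
            ),
            bounds=(-6, 2),
            method="bounded",
        )
        D_oracle = 10.0**res.x
        assert mix.D[0] == pytest.approx(D_oracle, rel=1e-3)
        assert mix.D[0] == pytest.approx(0.05, rel=0.03)
        assert mix.fractions["c"][0] == pytest.approx(1.0, abs=1e-6)

    def test_identical_conditions_identical_fractions(self):
        dt = 0.024
        sqd = draw_squared_displacements(
            [(0.01, 0.4), (0.2, 0.6)], 20000, dt, seed=5
        )
        mix = fit_sqd_mixture_global(
            {"a": sqd, "b": sqd.copy()}, n_components=2, frame_interval=dt
        )
        assert np.allclose(mix.fractions["a"], mix.fractions["b"], atol=1e-4)

    def test_fractions_sum_to_one_and_bounded(self):
        dt = 0.024
        sqd = {
            "x": draw_squared_displacements(
                [(0.01, 0.3), (0.1, 0.5), (1.0, 0.2)], 30000, dt, seed=6
            )
        }
        mix = fit_sqd_mixture_global(sqd, n_components=3, frame_interval=dt)
        f = mix.fractions["x"]
        assert f.sum() == pytest.approx(1.0, abs=1e-6)
        assert ((f >= 0) & (f <= 1)).all()
        assert (np.diff(mix.D) > 0).all()

    def test_recovery_error_shrinks_with_n(self):
        """|D̂ − D| shrinks in expectation from n=10³ to n=10⁵ (10 seeds)."""
        dt, D = 0.024, 0.05
        errs = {n: [] for n in (1000, 100000)}
        for s in range(10):
            for n in errs:
                sqd = draw_squared_displacements([(D, 1.0)], n, dt, seed=100 + s)
                mix = fit_sqd_mixture_global(
                    {"c": sqd}, n_components=1, frame_interval=dt, n_starts=3
                )
                errs[n].append(abs(mix.D[0] - D))
        assert np.mean(errs[100000]) < np.mean(errs[1000])

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            fit_sqd_mixture_global({"c": np.ones(50)}, frame_interval=0.024)


class TestClassification:
    def test_wellseparated_states_agree_with_ground_truth(self):
        dt = 0.024
        cfg = SimConfig(components=[(0.005, 0.5), (0.5, 0.5)], frame_interval=dt,
                        n_tracks=400, loc_error_sd=0.0, seed=8,
                        bleach_prob_per_frame=0.05)
        ts = simulate_tracks(cfg)
        sqd = compute_squared_displacements(ts)
        mix = fit_sqd_mixture_global({ts.condition: sqd}, n_components=2,
                                     frame_interval=dt)
        classify_tracks(ts, mix)
        labeled = [t for t in ts.tracks if t.motion_label is not None]
        agree = np.mean(
            [
                (t.motion_label == "confined") == (t.state_label == 0)
                for t in labeled
            ]
        )
        assert agree >= 0.9

    def test_single_point_tracks_unlabeled(self):
        ts = TrackSet(tracks=[make_track(0, [(0.0, 0.0)])], frame_interval=0.024,
                      condition="c")
        sqd = draw_squared_displacements([(0.05, 1.0)], 1000, 0.024, seed=1)
        mix = fit_sqd_mixture_global({"c": sqd}, n_components=1, frame_interval=0.024)
        classify_tracks(ts, mix)
        assert ts.tracks[0].motion_label is None

    def test_empty_trackset_ok(self):
        ts = TrackSet(tracks=[], frame_interval=0.024, condition="c")
        sqd = draw_squared_displacements([(0.05, 1.0)], 1000, 0.024, seed=1)
        mix = fit_sqd_mixture_global({"c": sqd}, n_components=1, frame_interval=0.024)
        assert len(classify_tracks(ts, mix)) == 0
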