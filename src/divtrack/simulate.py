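"""Synthetic data generators for SPT, dwell-time and FRAP analyses.

The simulator emulates the statistical structure the downstream estimators
assume: 2D multi-state Brownian motion with a fixed diffusive state per
molecule, Gaussian localization error, photobleaching-limited (geometric)
track lengths, reflecting cell boundaries, frame-discretized dwell
durations, and FRAP recovery curves with acquisition bleaching. Every
generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import CellGeometry
from .tracks import Track, TrackSet

__all__ = [
    "SimConfig",
    "simulate_tracks",
    "draw_squared_displacements",
    "simulate_dwell_durations",
    "simulate_frap_series",
]


@dataclass
class SimConfig:
    """Parameters of a multi-state Brownian track simulation.

    components : sequence of (D, fraction)
        Diffusion coefficient (µm²/s) and population fraction of each
        diffusive state. Fractions must sum to 1; each track is assigned one
        state for its whole lifetime.
    frame_interval : float
        Seconds between frames (0.024 or 0.009 for the acquisitions this
        emulates).
    loc_error_sd : float
        Gaussian localization error per axis, µm. 0.02 is a typical TMR
        single-molecule precision.
    bleach_prob_per_frame : float
        Per-frame termination probability; track lengths are geometric with
        mean 1/p. If 0, every track has ``max_frames`` localizations.
    geometry : CellGeometry or None
        Reflecting boundary; None simulates unbounded motion started at the
        origin.
    """

    components: Sequence[tuple[float, float]]
    frame_interval: float
    n_tracks: int
    loc_error_sd: float = 0.02
    bleach_prob_per_frame: float = 0.05
    geometry: Optional[CellGeometry] = None
    seed: int = 0
    max_frames: int = 1000
    condition: str = "simulated"
    markov_switching: bool = field(default=False)  # reserved; off by default

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("components must be non-empty")
        ds = np.array([d for d, _ in self.components], dtype=float)
        fs = np.array([f for _, f in self.components], dtype=float)
        if (ds < 0).any():
            raise ValueError("diffusion coefficients must be >= 0")
        if (fs < 0).any() or abs(fs.sum() - 1.0) > 1e-9:
            raise ValueError("component fractions must be >= 0 and sum to 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0 <= self.bleach_prob_per_frame < 1):
            raise ValueError("bleach_prob_per_frame must be in [0, 1)")
        if self.n_tracks <= 0:
            raise ValueError("n_tracks must be positive")
        if self.markov_switching:
            raise NotImplementedError("state switching is not used by any analysis")


def _track_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.bleach_prob_per_frame == 0:
        return np.full(cfg.n_tracks, cfg.max_frames, dtype=np.int64)
    lengths = rng.geometric(cfg.bleach_prob_per_frame, cfg.n_tracks)
    return np.minimum(lengths, cfg.max_frames).astype(np.int64)


def simulate_tracks(config: SimConfig) -> TrackSet:
    """Simulate a TrackSet of 2D Brownian tracks per the configuration.

    Per-frame displacements are isotropic Gaussian with variance
    2·D·frame_interval per axis; with a geometry the walk starts uniformly
    inside the cell and is reflected specularly at the outline; localization
    error is added after the walk (so reflection applies to true positions).
    """
    rng = np.random.default_rng(config.seed)
    fractions = np.array([f for _, f in config.components], dtype=float)
    dvals = np.array([d for d, _ in config.components], dtype=float)

    lengths = _track_lengths(config, rng)
    states = rng.choice(len(fractions), size=config.n_tracks, p=fractions)

    tracks: list[Track] = []
    for i in range(config.n_tracks):
        n = int(lengths[i])
        sigma_step = math.sqrt(2.0 * dvals[states[i]] * config.frame_interval)
        if config.geometry is None:
            steps = rng.normal(0.0, sigma_step, (n - 1, 2)) if n > 1 else np.empty((0, 2))
            xy = np.vstack([np.zeros((1, 2)), steps]).cumsum(axis=0)
        else:
            xy = np.empty((n, 2))
            xy[0] = config.geometry.sample_uniform(1, rng)[0]
            for j in range(1, n):
                prop = xy[j - 1] + rng.normal(0.0, sigma_step, 2)
                xy[j] = config.geometry.reflect(prop)
        if config.loc_error_sd > 0:
            xy = xy + rng.normal(0.0, config.loc_error_sd, xy.shape)
        tracks.append(
            Track(track_id=i, frames=np.arange(n), xy=xy, state_label=int(states[i]))
        )
    return TrackSet(tracks=tracks, frame_interval=config.frame_interval,
                    condition=config.condition)


def draw_squared_displacements(
    components: Sequence[tuple[float, float]],
    n_steps: int,
    frame_interval: float,
    seed: int = 0,
    loc_error_sd: float = 0.0,
) -> np.ndarray:
    """Draw squared frame-to-frame displacements from the mixture law.

    Under 2D Brownian motion with localization error σ on each endpoint,
    a single-frame squared displacement is exponential with mean
    4·D·Δt + 4·σ²; a population mixture draws the component per step.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    fractions = np.array([f for _, f in components], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    means = np.array(
        [4.0 * d * frame_interval + 4.0 * loc_error_sd**2 for d, _ in components]
    )
    comp = rng.choice(len(fractions), size=n_steps, p=fractions)
    return rng.exponential(means[comp])


def simulate_dwell_durations(
    p1: float,
    tau1: float,
    tau2: float,
    n: int,
    frame_interval: float,
    seed: int = 0,
) -> np.ndarray:
    """Frame-discretized dwell durations from a two-exponential mixture.

    Each duration is exponential with mean tau1 (probability p1) or tau2,
    then ceiled to an integer multiple of the frame interval: an event
    observed over k frames has duration k·Δt.
    """
    if not 0 <= p1 <= 1:
        raise ValueError("p1 must be in [0, 1]")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    taus = np.where(rng.random(n) < p1, tau1, tau2)
    x = rng.exponential(taus)
    k = np.ceil(x / frame_interval)
    durations = k * frame_interval
    return durations[durations > 0]


def simulate_frap_series(
    A: float,
    tau: float,
    pre_frames: int = 5,
    post_frames: int = 30,
    interval: float = 20.0,
    acq_bleach_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    anchor_offset: Optional[float] = None,
    pre_ratio: float = 0.4,
    floor_ratio: float = 0.1,
    cell_intensity: float = 1.0e6,
    roi_area: float = 40.0,
    cell_area: float = 400.0,
    background_mean: float = 50.0,
) -> pd.DataFrame:
    """Simulate a raw FRAP measurement table.

    The focus-to-cell CTCF ratio sits at ``pre_ratio`` before the bleach,
    drops instantaneously to ``floor_ratio`` and recovers as
    A·(1 − exp(−τ·t)) on the normalized scale, with t measured from the
    normalization anchor one ``anchor_offset`` (default: one frame interval)
    after the bleach. Both channels decay with ``acq_bleach_rate`` during
    acquisition, which the ratio normalization must cancel. Gaussian noise
    of sd ``noise_sd`` is applied on the normalized scale.

    Returns a table with columns time_s, roi_integrated_density, roi_area,
    background_mean, cell_integrated_density, cell_area, bleach (0 before /
    1 from the first post-bleach frame).
    """
    if not 0 <= A <= 1:
        raise ValueError("A must be in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if anchor_offset is None:
        anchor_offset = interval
    rng = np.random.default_rng(seed)

    n = pre_frames + post_frames
    t = np.arange(n) * interval
    t_bleach = t[pre_frames]
    t_anchor = t_bleach + anchor_offset

    # normalized recovery g: 1 pre-bleach, 0 at bleach..anchor, Eq-type rise after
    g = np.ones(n)
    post = t >= t_bleach
    g[post] = A * (1.0 - np.exp(-tau * np.clip(t[post] - t_anchor, 0.0, None)))
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, n)
    ratio = floor_ratio + (pre_ratio - floor_ratio) * g

    cell_ctcf = cell_intensity * np.exp(-acq_bleach_rate * t)
    focus_ctcf = ratio * cell_ctcf
    return pd.DataFrame(
        {
            "time_s": t,
            "roi_integrated_density": focus_ctcf + roi_area * background_mean,
            "roi_area": roi_area,
            "background_mean": background_mean,
            "cell_integrated_density": cell_ctcf + cell_area * background_mean,
            "cell_area": cell_area,
            "bleach": post.astype(int),
        }
    )
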