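"""Parameter-recovery experiments against the published DivIVA values.

Each function simulates data with a published parameter set as ground
truth, runs the corresponding estimator from this package, and returns the
fitted result. These are the building blocks of the recovery suite, the
acceptance script and the analysis drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import reference
from .diffusion import (
    DiffusionMixture,
    MSDFit,
    compute_ensemble_msd,
    fit_msd_linear,
    fit_sqd_mixture_global,
)
from .dwell import DwellFit, dwell_survival, fit_survival_biexponential
from .simulate import (
    SimConfig,
    draw_squared_displacements,
    simulate_dwell_durations,
    simulate_tracks,
)
from .track_io import filter_tracks

__all__ = [
    "MSDRecovery",
    "recover_msd_diffusion",
    "recover_population_fractions",
    "recover_dwell_row",
]


@dataclass
class MSDRecovery:
    true_D: float
    fit: MSDFit
    n_tracks: int
    n_pairs: int


def recover_msd_diffusion(
    true_D: float,
    frame_interval: float = reference.MSD_FRAME_INTERVAL,
    loc_error_sd: float = 0.02,
    n_tracks: int = 5000,
    mean_track_frames: float = 20.0,
    seed: int = 0,
    n_lags: int = 4,
) -> MSDRecovery:
    """Simulate unbounded single-state tracks and re-fit D from the MSD.

    Track lengths are geometric with the given mean (photobleaching-limited);
    tracks shorter than 5 frames are removed as in the real pipeline.
    """
    cfg = SimConfig(
        components=[(true_D, 1.0)],
        frame_interval=frame_interval,
        n_tracks=n_tracks,
        loc_error_sd=loc_error_sd,
        bleach_prob_per_frame=1.0 / mean_track_frames,
        seed=seed,
    )
    ts = filter_tracks(simulate_tracks(cfg), min_frames=5)
    curve = compute_ensemble_msd(ts, n_lags=n_lags)
    return MSDRecovery(
        true_D=true_D,
        fit=fit_msd_linear(curve),
        n_tracks=len(ts),
        n_pairs=int(curve.n_pairs.sum()),
    )


def recover_population_fractions(
    comparison: str,
    n_steps: int = 40000,
    state_D=reference.DEFAULT_STATE_D,
    seed: int = 0,
    n_boot: int = 0,
) -> DiffusionMixture:
    """Simulate SQD mixtures for a published comparison and re-fit globally.

    Every condition of the comparison is simulated with its published
    (confined, slow, fast) fractions over the shared per-state diffusion
    constants, then fitted jointly with shared D and free per-condition
    fractions, as the published analysis prescribes.
    """
    frame_interval, sets = reference.POPULATION_COMPARISONS[comparison]
    rng = np.random.default_rng(seed)
    sqd = {}
    for ps in sets:
        # published percentages round to ~0.1%, so close the simplex exactly
        f = np.array(ps.fractions)
        comps = list(zip(state_D, f / f.sum()))
        sqd[ps.condition] = draw_squared_displacements(
            comps, n_steps, frame_interval, seed=int(rng.integers(2**31))
        )
    return fit_sqd_mixture_global(
        sqd,
        n_components=len(state_D),
        frame_interval=frame_interval,
        seed=int(rng.integers(2**31)),
        n_boot=n_boot,
    )


def recover_dwell_row(
    row: reference.DwellRow,
    n: int = 10000,
    seed: int = 0,
    n_boot: int = 0,
) -> DwellFit:
    """Sample a published dwell row, discretize to frames, and re-fit."""
    durations = simulate_dwell_durations(
        p1=row.p1 / 100.0,
        tau1=row.tau1,
        tau2=row.tau2,
        n=n,
        frame_interval=row.frame_interval,
        seed=seed,
    )
    curve = dwell_survival(durations, frame_interval=row.frame_interval)
    return fit_survival_biexponential(curve, seed=seed, n_boot=n_boot)
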