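"""Displacement statistics and diffusion-model fits.

Two complementary estimators are implemented:

* the ensemble mean-squared displacement (MSD) over the first few lag
  times, fitted with a straight line ``MSD(τ) = 4·D·τ + b`` whose free
  intercept absorbs the 4σ² localization-error offset; and
* the cumulative distribution of squared frame-to-frame displacements
  (SQD / jump-distance analysis), fitted with a mixture of up to three
  diffusive states, ``F(u) = 1 − Σ_i f_i·exp(−u / (4·D_i·Δt))``, where the
  diffusion constants D_i are shared across all compared conditions and the
  fractions f_i are free per condition.

Both operate on gap-free displacement pairs, and the final localization of
each track is excluded to avoid track-ending artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import lmfit
import numpy as np
from scipy import stats

from .tracks import Track, TrackSet

__all__ = [
    "MSDCurve",
    "MSDFit",
    "DiffusionMixture",
    "compute_squared_displacements",
    "compute_ensemble_msd",
    "fit_msd_linear",
    "fit_sqd_mixture_global",
    "classify_tracks",
]

_STATE_NAMES = ("confined", "slow", "fast")


@dataclass
class MSDCurve:
    """Ensemble MSD at a few lag times (seconds → µm²)."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if not (np.diff(self.lags) > 0).all():
            raise ValueError("lags must be strictly increasing")


@dataclass
class MSDFit:
    """Linear MSD fit: D = slope/4 (2D), intercept absorbs 4σ²."""

    D: float
    intercept: float
    r_squared: float


@dataclass
class DiffusionMixture:
    """Globally fitted diffusive-state mixture.

    ``D`` is sorted ascending and shared across conditions; ``fractions``
    maps each condition to its population fractions (same order as D,
    summing to 1). Component labels follow ascending D: confined, slow,
    fast.
    """

    D: np.ndarray
    fractions: dict[str, np.ndarray]
    frame_interval: float
    n_steps: dict[str, int]
    D_se: Optional[np.ndarray] = None
    fractions_se: Optional[dict[str, np.ndarray]] = None
    residual: float = float("nan")

    @property
    def n_components(self) -> int:
        return len(self.D)

    @property
    def labels(self) -> tuple[str, ...]:
        return _STATE_NAMES[: self.n_components]


def _eligible_pairs(track: Track, lag_frames: int) -> np.ndarray:
    """Squared displacements over exactly ``lag_frames`` gap-free frames.

    The track's final localization is dropped before pairs are formed, and a
    pair is eligible only if every intermediate frame is present (a gapped
    step is not a true k-frame jump).
    """
    frames = track.frames[:-1]
    xy = track.xy[:-1]
    n = len(frames)
    if n < lag_frames + 1:
        return np.empty(0)
    contiguous = np.diff(frames) == 1
    if lag_frames == 1:
        ok = contiguous
    else:
        # all lag_frames consecutive diffs equal to 1
        c = np.concatenate([[0], np.cumsum(contiguous)])
        ok = (c[lag_frames:] - c[:-lag_frames]) == lag_frames
    d = xy[lag_frames:] - xy[:-lag_frames]
    return (d[ok] ** 2).sum(axis=1)


def compute_squared_displacements(
    trackset: TrackSet, lag_frames: int = 1
) -> np.ndarray:
    """Pool squared displacements at one lag over all tracks (µm²)."""
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    chunks = [_eligible_pairs(tr, lag_frames) for tr in trackset.tracks]
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def compute_ensemble_msd(trackset: TrackSet, n_lags: int = 4) -> MSDCurve:
    """Ensemble MSD at lags 1..n_lags frames, pooled over eligible pairs."""
    lags, msd, npairs = [], [], []
    for k in range(1, n_lags + 1):
        sq = compute_squared_displacements(trackset, lag_frames=k)
        if len(sq) == 0:
            warnings.warn(f"no eligible pairs at lag {k}; lag omitted", stacklevel=2)
            continue
        lags.append(k * trackset.frame_interval)
        msd.append(float(sq.mean()))
        npairs.append(len(sq))
    if not lags:
        raise ValueError("no eligible displacement pairs at any lag")
    return MSDCurve(lags=np.array(lags), msd=np.array(msd), n_pairs=np.array(npairs))


def fit_msd_linear(msd_curve: MSDCurve) -> MSDFit:
    """Ordinary least-squares line through the MSD curve; D = slope/4."""
    if len(msd_curve.lags) < 2:
        raise ValueError("need at least 2 lags for a linear MSD fit")
    res = stats.linregress(msd_curve.lags, msd_curve.msd)
    return MSDFit(D=res.slope / 4.0, intercept=res.intercept,
                  r_squared=res.rvalue**2)


# ---------------------------------------------------------------------------
# SQD mixture fitting


def _ecdf_points(sqd: np.ndarray, max_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support, thinned to at most ``max_points`` quantiles."""
    u = np.sort(sqd)
    n = len(u)
    probs = (np.arange(n) + 0.5) / n  # Hazen plotting positions
    if n > max_points:
        idx = np.unique(np.linspace(0, n - 1, max_points).round().astype(int))
        u, probs = u[idx], probs[idx]
    return u, probs


def _fractions_from_theta(theta: np.ndarray) -> np.ndarray:
    """Stick-breaking map from unconstrained [0,1] thetas to a simplex."""
    fractions = np.empty(len(theta) + 1)
    rest = 1.0
    for i, th in enumerate(theta):
        fractions[i] = rest * th
        rest *= 1.0 - th
    fractions[-1] = rest
    return fractions


def _mixture_cdf(u: np.ndarray, D: np.ndarray, f: np.ndarray, dt: float) -> np.ndarray:
    scales = 4.0 * np.maximum(D, 1e-12) * dt
    return 1.0 - (f[None, :] * np.exp(-u[:, None] / scales[None, :])).sum(axis=1)


def _fit_once(
    data: list[tuple[np.ndarray, np.ndarray]],
    conditions: list[str],
    d_start: np.ndarray,
    theta_start: Mapping[str, np.ndarray],
    dt: float,
) -> lmfit.minimizer.MinimizerResult:
    k = len(d_start)
    params = lmfit.Parameters()
    for i, d0 in enumerate(d_start):
        params.add(f"logD{i}", value=np.log10(d0), min=-6, max=2)
    for ci, cond in enumerate(conditions):
        for j in range(k - 1):
            params.add(f"th_{ci}_{j}", value=theta_start[cond][j], min=1e-6, max=1 - 1e-6)

    def residual(p):
        D = np.array([10.0 ** p[f"logD{i}"].value for i in range(k)])
        res = []
        for ci, (u, probs) in enumerate(data):
            theta = np.array([p[f"th_{ci}_{j}"].value for j in range(k - 1)])
            f = _fractions_from_theta(theta)
            res.append(_mixture_cdf(u, D, f, dt) - probs)
        return np.concatenate(res)

    return lmfit.minimize(residual, params, method="leastsq")


def _unpack(result, conditions, k, dt):
    D = np.array([10.0 ** result.params[f"logD{i}"].value for i in range(k)])
    fracs = {}
    for ci, cond in enumerate(conditions):
        theta = np.array(
            [result.params[f"th_{ci}_{j}"].value for j in range(k - 1)]
        )
        fracs[cond] = _fractions_from_theta(theta)
    order = np.argsort(D, kind="stable")
    return D[order], {c: f[order] for c, f in fracs.items()}


def fit_sqd_mixture_global(
    sqd_by_condition: Mapping[str, np.ndarray],
    n_components: int = 3,
    frame_interval: float = 0.024,
    n_starts: int = 8,
    n_boot: int = 0,
    seed: int = 0,
    max_cdf_points: int = 2000,
    min_steps: int = 200,
    collapse_tol: float = 1.5,
) -> DiffusionMixture:
    """Global least-squares fit of the cumulative SQD mixture model.

    Diffusion constants are shared across all conditions; per-condition
    fractions live on the simplex via a stick-breaking parameterization.
    Multi-start initialization log-spaces the D starts over [1e-4, 10]
    µm²/s; the best (lowest residual) fit is kept. Bootstrap standard
    errors (``n_boot`` resamples of each condition's steps) are optional.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1..3")
    conditions = list(sqd_by_condition)
    arrays = {c: np.asarray(sqd_by_condition[c], dtype=float) for c in conditions}
    for c, a in arrays.items():
        if len(a) < min_steps:
            raise ValueError(
                f"condition {c!r} has {len(a)} steps; need >= {min_steps}"
            )
    data = [_ecdf_points(arrays[c], max_cdf_points) for c in conditions]
    rng = np.random.default_rng(seed)

    # deterministic log-spaced start plus jittered restarts
    base = np.logspace(-3, 0.5, n_components) if n_components > 1 else np.array([0.05])
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(np.sort(10.0 ** rng.uniform(-4, 1, n_components)))
    theta0 = {c: np.full(max(n_components - 1, 0), 0.5) for c in conditions}

    best = None
    for d0 in starts:
        try:
            res = _fit_once(data, conditions, d0, theta0, frame_interval)
        except Exception:  # singular start; try the next one
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise RuntimeError("SQD mixture fit failed to converge from all starts")

    D, fracs = _unpack(best, conditions, n_components, frame_interval)
    if n_components > 1 and (D[1:] / np.maximum(D[:-1], 1e-300) < collapse_tol).any():
        warnings.warn(
            "fitted diffusion constants are nearly degenerate; "
            "consider reducing n_components",
            stacklevel=2,
        )

    D_se = None
    fr_se = None
    if n_boot > 0:
        boot_D = np.empty((n_boot, n_components))
        boot_f = {c: np.empty((n_boot, n_components)) for c in conditions}
        for b in range(n_boot):
            bdata = []
            for c in conditions:
                a = arrays[c]
                bdata.append(
                    _ecdf_points(a[rng.integers(0, len(a), len(a))], max_cdf_points)
                )
            th_start = {
                c: np.clip(_theta_from_fractions(fracs[c]), 1e-5, 1 - 1e-5)
                for c in conditions
            }
            try:
                rb = _fit_once(bdata, conditions, D, th_start, frame_interval)
                Db, fb = _unpack(rb, conditions, n_components, frame_interval)
            except Exception:
                Db, fb = D, fracs
            boot_D[b] = Db
            for c in conditions:
                boot_f[c][b] = fb[c]
        D_se = boot_D.std(axis=0, ddof=1)
        fr_se = {c: boot_f[c].std(axis=0, ddof=1) for c in conditions}

    return DiffusionMixture(
        D=D,
        fractions=fracs,
        frame_interval=frame_interval,
        n_steps={c: len(arrays[c]) for c in conditions},
        D_se=D_se,
        fractions_se=fr_se,
        residual=float(best.chisqr),
    )


def _theta_from_fractions(f: np.ndarray) -> np.ndarray:
    theta = np.empty(len(f) - 1)
    rest = 1.0
    for i in range(len(f) - 1):
        theta[i] = f[i] / rest if rest > 0 else 0.5
        rest -= f[i]
    return theta


def classify_tracks(trackset: TrackSet, mixture: DiffusionMixture) -> TrackSet:
    """Assign each track the diffusive state maximizing its step likelihood.

    Under state i the single-frame squared displacements of a track are
    i.i.d. exponential with mean 4·D_i·Δt, so the log-likelihood of a track
    with m steps summing to s is m·ln(1/μ_i) − s/μ_i (+ ln f_i prior).
    Tracks with no eligible steps stay unlabeled.
    """
    cond = trackset.condition
    f = mixture.fractions.get(cond)
    if f is None:  # condition not part of the fit: flat prior
        f = np.full(mixture.n_components, 1.0 / mixture.n_components)
    mu = 4.0 * np.maximum(mixture.D, 1e-12) * trackset.frame_interval
    log_prior = np.log(np.maximum(f, 1e-12))
    for tr in trackset.tracks:
        sq = _eligible_pairs(tr, 1)
        if len(sq) == 0:
            tr.motion_label = None
            continue
        m, s = len(sq), sq.sum()
        ll = -m * np.log(mu) - s / mu + log_prior
        tr.motion_label = mixture.labels[int(np.argmax(ll))]
    return trackset
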