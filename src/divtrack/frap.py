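"""FRAP quantification: CTCF, ratio normalization, recovery fit, statistics.

Intensities are background-corrected as CTCF = integrated density −
area·background. The focus CTCF is divided by the whole-cell CTCF to cancel
acquisition bleaching, then affinely rescaled so the pre-bleach mean maps
to 1 and the reference frame (one anchor offset, 20 s by default, after the
bleach) maps to 0 — the early post-bleach frames are excluded from fitting
to keep fluorophore photoswitching out of the kinetics. The recovery is
fitted with

    I(t) = A·(1 − exp(−τ·t)),   t measured from the anchor frame,

giving the mobile fraction A, immobile fraction 1 − A and half-time
recovery T½ = ln 2 / τ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FrapCurve",
    "FrapFit",
    "GroupComparison",
    "compute_ctcf",
    "normalize_frap",
    "fit_frap_recovery",
    "compare_groups",
]


def compute_ctcf(integrated_density, area, background_mean):
    """Corrected total cell fluorescence: integrated − area·background."""
    area = np.asarray(area, dtype=float)
    if (area < 0).any():
        raise ValueError("area must be non-negative")
    return np.asarray(integrated_density, dtype=float) - area * np.asarray(
        background_mean, dtype=float
    )


@dataclass
class FrapCurve:
    """Normalized FRAP series anchored at pre-bleach = 1, +offset frame = 0."""

    times: np.ndarray          # all frame times, s (acquisition clock)
    normalized: np.ndarray     # normalized ratio per frame
    fit_times: np.ndarray      # seconds from the anchor frame (t >= 0)
    fit_values: np.ndarray
    pre_value: float           # pre-bleach mean of the raw ratio
    anchor_value: float        # raw ratio at the anchor frame
    bleach_index: int
    anchor_index: int


@dataclass
class FrapFit:
    """Fitted recovery: mobile fraction A, rate τ (1/s), T½ = ln2/τ."""

    A: float
    tau: float
    t_half: float
    immobile: float
    r_squared: float
    residual_sd: float
    warnings: list = field(default_factory=list)


def normalize_frap(
    table: pd.DataFrame,
    bleach_frame: Optional[int] = None,
    ref_offset: float = 20.0,
) -> FrapCurve:
    """Normalize a raw FRAP table to the pre-bleach/post-bleach anchors.

    ``bleach_frame`` is the index of the first post-bleach frame; if None it
    is taken from a 0/1 ``bleach`` column. The whole-cell CTCF uses the
    optional ``cell_area`` column (without it the whole-cell signal is
    assumed to be background-corrected already).
    """
    df = table.reset_index(drop=True)
    if bleach_frame is None:
        if "bleach" not in df.columns:
            raise ValueError("bleach_frame not given and no 'bleach' column present")
        marks = np.nonzero(df["bleach"].to_numpy() > 0)[0]
        if len(marks) == 0:
            raise ValueError("bleach column never set")
        bleach_frame = int(marks[0])
    if bleach_frame < 1:
        raise ValueError("need at least one pre-bleach frame")

    t = df["time_s"].to_numpy(dtype=float)
    focus = compute_ctcf(
        df["roi_integrated_density"], df["roi_area"], df["background_mean"]
    )
    if "cell_area" in df.columns:
        cell = compute_ctcf(
            df["cell_integrated_density"], df["cell_area"], df["background_mean"]
        )
    else:
        cell = df["cell_integrated_density"].to_numpy(dtype=float)
    if np.any(cell == 0):
        raise ValueError("whole-cell CTCF is zero at some frame")
    ratio = focus / cell

    t_anchor = t[bleach_frame] + ref_offset
    after = np.nonzero(t >= t_anchor - 1e-9)[0]
    if len(after) == 0:
        raise ValueError("no frame at or after the +offset anchor")
    anchor_idx = int(after[0])

    pre = float(ratio[:bleach_frame].mean())
    anchor = float(ratio[anchor_idx])
    if abs(pre - anchor) < 1e-15:
        raise ValueError("degenerate anchors: pre-bleach equals anchor value")
    norm = (ratio - anchor) / (pre - anchor)
    return FrapCurve(
        times=t,
        normalized=norm,
        fit_times=t[anchor_idx:] - t[anchor_idx],
        fit_values=norm[anchor_idx:],
        pre_value=pre,
        anchor_value=anchor,
        bleach_index=bleach_frame,
        anchor_index=anchor_idx,
    )


def fit_frap_recovery(curve: FrapCurve, min_points: int = 5) -> FrapFit:
    """Nonlinear least squares of A·(1 − e^(−τt)) on the anchored series."""
    t, y = curve.fit_times, curve.fit_values
    if len(t) < min_points:
        raise ValueError(f"need >= {min_points} post-anchor frames, have {len(t)}")
    a0 = float(np.clip(np.mean(y[-max(3, len(y) // 4):]), 0.05, 2.0))
    # initial rate from the first crossing of half the plateau
    above = np.nonzero(y >= 0.5 * a0)[0]
    t50 = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
    p0 = (a0, math.log(2) / t50)
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, A, tau: A * (1.0 - np.exp(-tau * tt)),
            t,
            y,
            p0=p0,
            bounds=([0.0, 1e-9], [5.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"FRAP recovery fit did not converge: {exc}") from exc
    A, tau = float(popt[0]), float(popt[1])
    if tau <= 0:
        raise RuntimeError("non-positive recovery rate at optimum")
    resid = y - A * (1.0 - np.exp(-tau * t))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    warns = []
    if A > 1.0:
        warns.append("mobile fraction A exceeds 1 (fit-quality warning)")
    return FrapFit(
        A=A,
        tau=tau,
        t_half=math.log(2) / tau,
        immobile=1.0 - A,
        r_squared=r2,
        residual_sd=float(resid.std(ddof=1)) if len(resid) > 1 else float("nan"),
        warnings=warns,
    )


@dataclass
class GroupComparison:
    """Decision path and p-values of a many-to-one group comparison."""

    control: str
    shapiro_p: dict[str, float]
    bartlett_p: float
    parametric: bool
    test_name: str
    p_values: dict[str, float]
    alpha: float = 0.05

    @property
    def significant(self) -> dict[str, bool]:
        return {g: p < self.alpha for g, p in self.p_values.items()}


def compare_groups(
    samples: Mapping[str, np.ndarray],
    control: Optional[str] = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare treatment groups against a control, as the study's pipeline.

    Each group is tested for normality (Shapiro–Wilk) and the ensemble for
    homoscedasticity (Bartlett). If all pass at ``alpha``, treatments are
    compared to the control with Dunnett's many-to-one test (one-sided,
    alternative: location shift less than 0); otherwise each treatment is
    compared with the Wilcoxon rank-sum (Mann–Whitney) test with continuity
    correction, one-sided.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has {len(v)} values; need >= 3")
    if control is None:
        control = next(iter(groups))
    treatments = [g for g in groups if g != control]

    shapiro_p = {}
    degenerate = False
    for g, v in groups.items():
        if np.ptp(v) == 0:
            shapiro_p[g] = 0.0  # constant sample: not testably normal
            degenerate = True
        else:
            shapiro_p[g] = float(stats.shapiro(v).pvalue)
    if degenerate or any(np.ptp(v) == 0 for v in groups.values()):
        bartlett_p = 1.0
    else:
        bartlett_p = float(stats.bartlett(*groups.values()).pvalue)

    parametric = all(p > alpha for p in shapiro_p.values()) and bartlett_p > alpha
    p_values: dict[str, float] = {}
    if parametric:
        res = stats.dunnett(
            *[groups[g] for g in treatments],
            control=groups[control],
            alternative="less",
        )
        for g, p in zip(treatments, np.atleast_1d(res.pvalue)):
            p_values[g] = float(p)
        test_name = "Dunnett (one-sided, less)"
    else:
        for g in treatments:
            if np.ptp(groups[g]) == 0 and np.ptp(groups[control]) == 0 and (
                groups[g][0] == groups[control][0]
            ):
                p_values[g] = 1.0
                continue
            res = stats.mannwhitneyu(
                groups[g],
                groups[control],
                alternative="less",
                use_continuity=True,
                method="asymptotic",
            )
            p_values[g] = float(res.pvalue)
        test_name = "Wilcoxon rank-sum (continuity-corrected, one-sided, less)"
    return GroupComparison(
        control=control,
        shapiro_p=shapiro_p,
        bartlett_p=bartlett_p,
        parametric=parametric,
        test_name=test_name,
        p_values=p_values,
        alpha=alpha,
    )
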