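"""Config-driven orchestration of the SPT, FRAP and recovery analyses.

Configs are plain dictionaries (typically loaded from YAML). Every run
writes tidy CSV tables plus a machine-readable ``summary.json`` embedding
the config hash, seed and package version, so re-running an unchanged
config is byte-stable for the tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__, reference
from .diffusion import (
    classify_tracks,
    compute_ensemble_msd,
    compute_squared_displacements,
    fit_msd_linear,
    fit_sqd_mixture_global,
)
from .dwell import (
    confinement_heatmap,
    detect_dwell_events,
    dwell_survival,
    fit_survival_biexponential,
)
from .frap import compare_groups, fit_frap_recovery, normalize_frap
from .geometry import CellGeometry
from .recovery import (
    recover_dwell_row,
    recover_msd_diffusion,
    recover_population_fractions,
)
from .simulate import SimConfig, simulate_tracks
from .track_io import DEFAULT_DIALECT, filter_tracks, read_tracks, write_tracks

log = logging.getLogger("divtrack")

__all__ = ["validate_config", "run_spt_pipeline", "run_frap_pipeline",
           "run_recovery_suite"]


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: Mapping) -> dict:
    return {
        "config_hash": _config_hash(config),
        "seed": config.get("seed", 0),
        "version": __version__,
    }


_REQUIRED = {
    "spt": ("frame_interval",),
    "frap": ("inputs",),
    "recover": (),
    "simulate": ("frame_interval", "components", "n_tracks"),
}


def validate_config(config: Mapping, mode: str) -> None:
    """Fail fast on missing mode-required fields, before any compute."""
    if mode not in _REQUIRED:
        raise ValueError(f"unknown mode {mode!r}")
    missing = [k for k in _REQUIRED[mode] if k not in config]
    if missing:
        raise ValueError(f"config for mode {mode!r} missing fields: {missing}")


def _geometry_from_config(config: Mapping) -> Optional[CellGeometry]:
    g = config.get("geometry")
    if g is None:
        return None
    return CellGeometry(g["shape"], g["length"], g["width"])


def _load_or_simulate(config: Mapping):
    if "tracks_csv" in config:
        return read_tracks(
            config["tracks_csv"],
            frame_interval=config["frame_interval"],
            condition=config.get("condition", "default"),
            dialect=config.get("dialect", DEFAULT_DIALECT),
        )
    sim = SimConfig(
        components=[tuple(c) for c in config["components"]],
        frame_interval=config["frame_interval"],
        n_tracks=config["n_tracks"],
        loc_error_sd=config.get("loc_error_sd", 0.02),
        bleach_prob_per_frame=config.get("bleach_prob_per_frame", 0.05),
        geometry=_geometry_from_config(config),
        seed=config.get("seed", 0),
        condition=config.get("condition", "simulated"),
    )
    return simulate_tracks(sim)


def run_spt_pipeline(config: Mapping, outdir) -> dict:
    """Filter → MSD → global SQD mixture → classification → dwell → map.

    ``config`` needs ``frame_interval`` plus either ``tracks_csv`` or a
    simulation block (``components``, ``n_tracks``); see the bundled demo
    config. Returns the summary dict that is also written to
    ``summary.json``.
    """
    validate_config(config, "spt")
    if "tracks_csv" not in config:
        validate_config(config, "simulate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    ts = _load_or_simulate(config)
    log.info("loaded %d tracks (%d localizations)", len(ts), ts.n_localizations)
    ts = filter_tracks(
        ts,
        min_frames=config.get("min_frames", 5),
        max_gap_frames=config.get("max_gap_frames", 2),
    )
    write_tracks(ts, outdir / "tracks_filtered.csv")

    curve = compute_ensemble_msd(ts, n_lags=config.get("n_lags", 4))
    msd_fit = fit_msd_linear(curve)
    pd.DataFrame(
        {"lag_s": curve.lags, "msd_um2": curve.msd, "n_pairs": curve.n_pairs}
    ).to_csv(outdir / "msd_curve.csv", index=False)

    sqd = compute_squared_displacements(ts, lag_frames=1)
    mixture = fit_sqd_mixture_global(
        {ts.condition: sqd},
        n_components=config.get("n_components", 3),
        frame_interval=ts.frame_interval,
        seed=config.get("seed", 0),
        n_boot=config.get("n_boot", 0),
    )
    rows = []
    for c, fr in mixture.fractions.items():
        for lab, d, f in zip(mixture.labels, mixture.D, fr):
            rows.append((c, lab, d, f, mixture.n_steps[c]))
    pd.DataFrame(
        rows, columns=["condition", "component", "D_um2_s", "fraction", "n_steps"]
    ).to_csv(outdir / "sqd_mixture.csv", index=False)

    classify_tracks(ts, mixture)
    events = detect_dwell_events(
        ts,
        radius=config.get("confinement_radius", 0.097),
        min_event_frames=config.get("min_event_frames", 3),
    )
    dwell_summary = None
    if events:
        pd.DataFrame(
            [
                (e.track_id, e.start_frame, e.n_frames, e.duration, e.censored)
                for e in events
            ],
            columns=["track_id", "start_frame", "n_frames", "duration_s", "censored"],
        ).to_csv(outdir / "dwell_events.csv", index=False)
        surv = dwell_survival(events, frame_interval=ts.frame_interval)
        pd.DataFrame({"t_s": surv.times, "survival": surv.survival}).to_csv(
            outdir / "dwell_survival.csv", index=False
        )
        if len(surv.times) >= 5:
            dfit = fit_survival_biexponential(surv, seed=config.get("seed", 0))
            dwell_summary = {
                "tau1_s": dfit.tau1,
                "p1": dfit.p1,
                "tau2_s": dfit.tau2,
                "p2": dfit.p2,
                "n_events": surv.n_events,
            }

    geometry = _geometry_from_config(config)
    if geometry is not None:
        cmap = confinement_heatmap(ts, geometry)
        np.savetxt(outdir / "confinement_map.csv", cmap.counts, delimiter=",")

    summary = {
        **_provenance(config),
        "condition": ts.condition,
        "n_tracks": len(ts),
        "msd": {
            "D_um2_s": msd_fit.D,
            "intercept_um2": msd_fit.intercept,
            "r_squared": msd_fit.r_squared,
        },
        "sqd_mixture": {
            "D_um2_s": mixture.D.tolist(),
            "fractions": {c: f.tolist() for c, f in mixture.fractions.items()},
        },
        "dwell": dwell_summary,
    }
    log.info("SPT pipeline finished in %.2f s", time.time() - t_start)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_frap_pipeline(config: Mapping, outdir) -> dict:
    """Per-cell normalization + recovery fits, then the group comparison.

    ``config["inputs"]`` maps group name → list of per-cell FRAP CSV paths.
    Per-cell fit failures are recorded and the pipeline continues.
    """
    validate_config(config, "frap")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    halftimes: dict[str, list[float]] = {}
    failures: list[dict] = []
    for group, paths in config["inputs"].items():
        halftimes[group] = []
        for p in paths:
            try:
                curve = normalize_frap(
                    pd.read_csv(p), ref_offset=config.get("ref_offset", 20.0)
                )
                fit = fit_frap_recovery(curve)
            except Exception as exc:
                failures.append({"group": group, "path": str(p), "error": str(exc)})
                continue
            rows.append(
                (group, str(p), fit.A, fit.tau, fit.t_half, fit.immobile, fit.r_squared)
            )
            halftimes[group].append(fit.t_half)
    fits = pd.DataFrame(
        rows, columns=["group", "path", "A", "tau_per_s", "t_half_s", "immobile", "r_squared"]
    )
    fits.to_csv(outdir / "frap_fits.csv", index=False)

    comparison = None
    usable = {g: v for g, v in halftimes.items() if len(v) >= 3}
    if len(usable) >= 2:
        comp = compare_groups(
            {g: np.array(v) for g, v in usable.items()},
            control=config.get("control"),
        )
        comparison = {
            "control": comp.control,
            "test": comp.test_name,
            "parametric": comp.parametric,
            "shapiro_p": comp.shapiro_p,
            "bartlett_p": comp.bartlett_p,
            "p_values": comp.p_values,
        }
    else:
        log.info("fewer than two usable groups; comparison skipped")

    summary = {
        **_provenance(config),
        "n_cells_fit": len(fits),
        "failures": failures,
        "group_t_half_mean_s": {g: float(np.mean(v)) for g, v in usable.items()},
        "comparison": comparison,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_recovery_suite(config: Mapping, outdir) -> dict:
    """Simulate with the published values, re-estimate, compare to truth.

    Covers the MSD diffusion coefficients, every published jump-distance
    population comparison, and every dwell-table row; each entry records
    truth, estimate and pass/fail at its tolerance.
    """
    validate_config(config, "recover")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    entries = []

    for name, true_D in reference.MSD_COEFFICIENTS.items():
        rec = recover_msd_diffusion(true_D, seed=int(rng.integers(2**31)))
        tol = 0.10 if true_D > 0.05 else 0.15
        entries.append(
            {
                "quantity": f"msd_D_{name}",
                "truth": true_D,
                "estimate": rec.fit.D,
                "tolerance_rel": tol,
                "ok": abs(rec.fit.D - true_D) <= tol * true_D,
            }
        )

    for comparison, (_, sets) in reference.POPULATION_COMPARISONS.items():
        mix = recover_population_fractions(comparison, seed=int(rng.integers(2**31)))
        for ps in sets:
            for lab, truth, est in zip(
                ("confined", "slow", "fast"), ps.fractions, mix.fractions[ps.condition]
            ):
                entries.append(
                    {
                        "quantity": f"fraction_{comparison}_{ps.condition}_{lab}",
                        "truth": truth * 100,
                        "estimate": est * 100,
                        "tolerance_pp": 3.0,
                        "ok": abs(est - truth) * 100 <= 3.0,
                    }
                )

    for row in reference.DWELL_TABLE:
        fit = recover_dwell_row(row, seed=int(rng.integers(2**31)))
        tau_tol = 0.10 if row.frame_interval >= 0.02 else 0.15
        entries.append(
            {
                "quantity": f"dwell_tau2_{row.condition}",
                "truth": row.tau2,
                "estimate": fit.tau2,
                "tolerance_rel": tau_tol,
                "ok": abs(fit.tau2 - row.tau2) <= tau_tol * row.tau2,
            }
        )
        entries.append(
            {
                "quantity": f"dwell_p2_{row.condition}",
                "truth": row.p2,
                "estimate": fit.p2 * 100,
                "tolerance_pp": 5.0,
                "ok": abs(fit.p2 * 100 - row.p2) <= 5.0,
            }
        )

    report = {
        **_provenance(config),
        "n_pass": sum(e["ok"] for e in entries),
        "n_total": len(entries),
        "entries": entries,
    }
    (outdir / "recovery_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    return report
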