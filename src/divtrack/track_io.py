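"""Reading, writing and filtering of track tables.

Track tables are CSV files with one row per localization (track id, frame,
x, y). The internal dialect uses columns ``track_id, frame, x, y`` in µm;
TrackMate spot exports (``TRACK_ID, FRAME, POSITION_X, POSITION_Y`` with
three extra header rows) are supported through :data:`TRACKMATE_DIALECT`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = [
    "TrackTableDialect",
    "DEFAULT_DIALECT",
    "TRACKMATE_DIALECT",
    "TrackFormatError",
    "TrackIntegrityError",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
]


class TrackFormatError(ValueError):
    """Malformed track table (missing column, non-numeric value)."""


class TrackIntegrityError(ValueError):
    """Structurally valid table violating track semantics (duplicate frames)."""


@dataclass(frozen=True)
class TrackTableDialect:
    """Column mapping and units of a track-table CSV flavour."""

    track_col: str = "track_id"
    frame_col: str = "frame"
    x_col: str = "x"
    y_col: str = "y"
    unit: str = "um"  # "um" or "nm"
    extra_header_rows: int = 0

    def __post_init__(self) -> None:
        if self.unit not in ("um", "nm"):
            raise ValueError("unit must be 'um' or 'nm'")


DEFAULT_DIALECT = TrackTableDialect()
#: TrackMate "spots" CSV export: three sub-header rows follow the header.
TRACKMATE_DIALECT = TrackTableDialect(
    track_col="TRACK_ID",
    frame_col="FRAME",
    x_col="POSITION_X",
    y_col="POSITION_Y",
    unit="um",
    extra_header_rows=3,
)


def read_tracks(
    path,
    frame_interval: float,
    condition: str = "default",
    dialect: TrackTableDialect = DEFAULT_DIALECT,
) -> TrackSet:
    """Read a track CSV into a TrackSet, grouping by track id.

    Localizations are sorted by frame within each track; nm coordinates are
    converted to µm; duplicate (track, frame) rows raise
    :class:`TrackIntegrityError`.
    """
    path = Path(path)
    skip = range(1, 1 + dialect.extra_header_rows) if dialect.extra_header_rows else None
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if df.empty and len(df.columns) <= 1:
        warnings.warn(f"{path} contains no track data", stacklevel=2)
        return TrackSet(tracks=[], frame_interval=frame_interval, condition=condition)
    needed = {
        "track id": dialect.track_col,
        "frame": dialect.frame_col,
        "x": dialect.x_col,
        "y": dialect.y_col,
    }
    for role, col in needed.items():
        if col not in df.columns:
            raise TrackFormatError(f"missing {role} column {col!r} in {path}")
    sub = df[[dialect.track_col, dialect.frame_col, dialect.x_col, dialect.y_col]].copy()
    sub.columns = ["track_id", "frame", "x", "y"]
    for col in ("frame", "x", "y"):
        vals = pd.to_numeric(sub[col], errors="coerce")
        if vals.isna().any() and not sub[col].isna().any():
            bad = sub.loc[vals.isna(), col].iloc[0]
            raise TrackFormatError(f"non-numeric value {bad!r} in column {col!r}")
        if vals.isna().any():
            raise TrackFormatError(f"missing value in column {col!r}")
        sub[col] = vals
    if sub.empty:
        warnings.warn(f"{path} contains no track data", stacklevel=2)
        return TrackSet(tracks=[], frame_interval=frame_interval, condition=condition)
    if sub.duplicated(subset=["track_id", "frame"]).any():
        raise TrackIntegrityError(f"duplicate (track, frame) rows in {path}")
    scale = 1e-3 if dialect.unit == "nm" else 1.0
    tracks = []
    for tid, grp in sub.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=tid,
                frames=grp["frame"].to_numpy(dtype=np.int64),
                xy=grp[["x", "y"]].to_numpy(dtype=float) * scale,
            )
        )
    return TrackSet(tracks=tracks, frame_interval=frame_interval, condition=condition)


def write_tracks(trackset: TrackSet, path) -> None:
    """Write a TrackSet to the internal CSV dialect.

    Rows are ordered by (track id, frame) and coordinates written at full
    double precision, so write→read round-trips losslessly and repeated
    writes are byte-identical.
    """
    rows = []
    for tr in trackset.tracks:
        for f, (x, y) in zip(tr.frames, tr.xy):
            rows.append((tr.track_id, int(f), x, y))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    if len(df):
        df = df.sort_values(["track_id", "frame"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def _split_at_gaps(track: Track, max_gap_frames: int) -> list[Track]:
    gaps = np.diff(track.frames) - 1
    cut = np.nonzero(gaps > max_gap_frames)[0]
    if len(cut) == 0:
        return [track]
    pieces = []
    start = 0
    bounds = list(cut + 1) + [len(track.frames)]
    for k, stop in enumerate(bounds):
        pieces.append(
            Track(
                track_id=f"{track.track_id}.{k}" if len(bounds) > 1 else track.track_id,
                frames=track.frames[start:stop],
                xy=track.xy[start:stop],
                state_label=track.state_label,
            )
        )
        start = stop
    return pieces

def filter_tracks(
    trackset: TrackSet, min_frames: int = 5, max_gap_frames: int = 2
) -> TrackSet:
    """Split tracks at gaps longer than ``max_gap_frames`` and drop short ones.

    "Length" is the frame span (last − first + 1). Gaps up to
    ``max_gap_frames`` are retained inside a track (displacement statistics
    exclude pairs bridging them); longer gaps split the track before the
    length filter is applied. The returned TrackSet carries a ``report``
    dict listing dropped and split track ids.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    kept: list[Track] = []
    dropped: list = []
    split: list = []
    for tr in trackset.tracks:
        pieces = _split_at_gaps(tr, max_gap_frames)
        if len(pieces) > 1:
            split.append(tr.track_id)
        for p in pieces:
            if p.span_frames >= min_frames:
                kept.append(p)
            else:
                dropped.append(p.track_id)
    out = TrackSet(
        tracks=kept,
        frame_interval=trackset.frame_interval,
        condition=trackset.condition,
    )
    out.report = {
        "n_in": len(trackset.tracks),
        "n_out": len(kept),
        "dropped": dropped,
        "split": split,
        "min_frames": min_frames,
        "max_gap_frames": max_gap_frames,
    }
    return out
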