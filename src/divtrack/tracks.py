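"""Core containers for single-particle tracking data.

A :class:`Track` is the ordered sequence of localizations of one molecule
(frame index plus x/y in µm); a :class:`TrackSet` bundles tracks acquired
under one condition at one frame interval. These are the substrate of all
displacement, dwell and mixture statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterator, Optional

import numpy as np


@dataclass
class Track:
    """Ordered localizations of a single molecule.

    frames must be strictly increasing integers; xy is an (n, 2) float array
    in µm. ``state_label`` carries the ground-truth diffusive component for
    simulated tracks; ``motion_label`` is filled in by classification
    (confined / slow / fast).
    """

    track_id: Hashable
    frames: np.ndarray
    xy: np.ndarray
    state_label: Optional[int] = None
    motion_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or len(self.frames) == 0:
            raise ValueError("track needs at least one localization")
        if self.xy.shape != (len(self.frames), 2):
            raise ValueError("xy must be (n_frames, 2)")
        if len(self.frames) > 1 and not (np.diff(self.frames) > 0).all():
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_localizations(self) -> int:
        return len(self.frames)

    @property
    def span_frames(self) -> int:
        """Number of frames spanned, last − first + 1 (linker semantics)."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def has_gaps(self) -> bool:
        return bool((np.diff(self.frames) > 1).any())


@dataclass
class TrackSet:
    """Tracks of one experimental condition at a fixed frame interval."""

    tracks: list[Track]
    frame_interval: float
    condition: str = "default"
    report: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self.condition:
            raise ValueError("condition label must be non-empty")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    @property
    def n_localizations(self) -> int:
        return sum(len(t) for t in self.tracks)
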