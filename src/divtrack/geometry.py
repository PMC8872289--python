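"""Cell geometries for trajectory simulation and confinement maps.

Rod-shaped cells are modelled as a 2D spherocylinder (a rectangle capped by
two semicircles) — the TIRF projection of the cell onto the focal plane.
Spheres (protoplasts, L-forms) are the degenerate case length == width.
Coordinates are in µm with the origin at the cell centre, the long axis
along x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_REFLECT_ITER = 64


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylindrical (rod) or spherical cell outline.

    Parameters
    ----------
    shape : {"rod", "sphere"}
    length : float
        Long-axis extent in µm, cap to cap. For a sphere this equals width.
    width : float
        Diameter of the short axis / sphere in µm.
    """

    shape: str
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.shape not in ("rod", "sphere"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        if self.shape == "sphere" and self.length != self.width:
            raise ValueError("sphere requires length == width")

    @classmethod
    def rod(cls, length: float, width: float) -> "CellGeometry":
        return cls("rod", length, width)

    @classmethod
    def sphere(cls, diameter: float) -> "CellGeometry":
        return cls("sphere", diameter, diameter)

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def half_axis(self) -> float:
        """Half-length of the centreline segment (0 for a sphere)."""
        return (self.length - self.width) / 2.0

    def _centreline_dist(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance of points to the centreline segment and the foot points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        cx = np.clip(xy[:, 0], -self.half_axis, self.half_axis)
        foot = np.column_stack([cx, np.zeros(len(xy))])
        d = np.hypot(xy[:, 0] - cx, xy[:, 1])
        return d, foot

    def contains(self, xy: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        """Boolean mask of points inside (or on) the outline."""
        d, _ = self._centreline_dist(xy)
        return d <= self.radius + atol

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the outline, by rejection from the bounding box."""
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = np.column_stack(
                [
                    rng.uniform(-self.length / 2, self.length / 2, m),
                    rng.uniform(-self.radius, self.radius, m),
                ]
            )
            good = cand[self.contains(cand)]
            take = min(len(good), n - filled)
            out[filled : filled + take] = good[:take]
            filled += take
        return out

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Specular reflection of points back inside the outline.

        Points beyond the boundary are mirrored across the outline along the
        surface normal (the radial direction from the nearest centreline
        point). Iterated so steps larger than the cell width still land
        inside.
        """
        p = np.atleast_2d(np.asarray(xy, dtype=float)).copy()
        for _ in range(_MAX_REFLECT_ITER):
            d, foot = self._centreline_dist(p)
            outside = d > self.radius
            if not outside.any():
                break
            u = (p[outside] - foot[outside]) / d[outside, None]
            p[outside] = foot[outside] + (2 * self.radius - d[outside, None]) * u
        else:  # pragma: no cover - pathological step sizes
            d, foot = self._centreline_dist(p)
            bad = d > self.radius
            u = (p[bad] - foot[bad]) / d[bad, None]
            p[bad] = foot[bad] + self.radius * 0.999 * u
        return p.reshape(np.shape(xy))
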