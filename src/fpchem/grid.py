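"""Uniform retention-time grids for detector traces.

A chromatographic fingerprint is sampled on a uniform time axis.  The
analysis window used throughout this package is 13.2-64.5 min sampled every
0.4 s (2.5 Hz), which gives 7696 absorbance measurements with inclusive
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default fingerprint analysis window (minutes).
DEFAULT_WINDOW_MIN: tuple[float, float] = (13.2, 64.5)
#: Default detector sampling interval (seconds), i.e. 2.5 Hz.
DEFAULT_SPACING_S: float = 0.4


@dataclass(frozen=True)
class TimeGrid:
    """Uniform, inclusive-endpoint retention-time grid.

    Parameters
    ----------
    start_min, end_min:
        Window endpoints in minutes.
    spacing_s:
        Sampling interval in seconds.
    points:
        Strictly increasing vector of time points (minutes); first point is
        ``start_min``, last is ``end_min``.
    """

    start_min: float
    end_min: float
    spacing_s: float
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("a TimeGrid needs at least two points")
        diffs = np.diff(pts)
        if np.any(diffs <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.max(np.abs(diffs - diffs[0])) > 1e-9:
            raise ValueError("grid spacing must be uniform within 1e-9 min")
        if abs(pts[0] - self.start_min) > 1e-9 or abs(pts[-1] - self.end_min) > 1e-9:
            raise ValueError("grid endpoints must match start_min/end_min")

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @property
    def spacing_min(self) -> float:
        """Sampling interval in minutes."""
        return self.spacing_s / 60.0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_points

    def isclose(self, other: "TimeGrid", tol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and np.max(np.abs(self.points - other.points)) <= tol
        )


def make_time_grid(start_min: float, end_min: float, spacing_s: float) -> TimeGrid:
    """Build a uniform grid with inclusive endpoints.

    The span must be an integer multiple of the spacing (within 1e-6 of a
    step); the point count is ``round(span_s / spacing_s) + 1``.  The default
    window ``(13.2, 64.5)`` at 0.4 s spacing yields 7696 points.
    """
    if end_min <= start_min:
        raise ValueError("end_min must exceed start_min")
    if spacing_s <= 0:
        raise ValueError("spacing_s must be positive")
    span_s = (end_min - start_min) * 60.0
    steps = span_s / spacing_s
    residual = abs(steps - round(steps))
    if residual > 1e-6:
        raise ValueError(
            f"window span {span_s:g} s is not divisible by spacing "
            f"{spacing_s:g} s (residual {residual:g} steps)"
        )
    n = int(round(steps)) + 1
    points = np.linspace(start_min, end_min, n)
    return TimeGrid(start_min=start_min, end_min=end_min, spacing_s=spacing_s, points=points)


def default_grid() -> TimeGrid:
    """The 13.2-64.5 min, 0.4 s (7696-point) analysis grid."""
    return make_time_grid(*DEFAULT_WINDOW_MIN, DEFAULT_SPACING_S)
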