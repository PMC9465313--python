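"""Time grids, linear interpolation and delay-grid construction.

All times are in hours. Interpolation is piecewise linear; queries outside
the measured range are clamped to the boundary knot value by default (the
delayed targets of the regression model can reach past the last measured
protein time point, and linear extrapolation there would produce unbounded
targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError

__all__ = [
    "TimeGrid",
    "Series",
    "DelayGrid",
    "build_delay_grid",
    "interpolate_linear",
    "align_timepoints",
]


@dataclass(frozen=True)
class TimeGrid:
    """An ordered grid of sampling times in hours.

    Times must be strictly increasing, non-negative and at least two.
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("TimeGrid needs at least two time points")
        if not np.all(np.isfinite(t)):
            raise ValueError("TimeGrid times must be finite")
        if t[0] < 0:
            raise ValueError("TimeGrid times must be non-negative")
        if not np.all(np.diff(t) > 0):
            raise ValueError("TimeGrid times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Series:
    """A real-valued trajectory sampled on a :class:`TimeGrid`."""

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("Series values must be one-dimensional")
        if v.size != len(self.grid):
            raise ValueError(
                f"Series has {v.size} values but grid has {len(self.grid)} times"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DelayGrid:
    """Candidate delays tau in hours, from 0 to ``t_max``.

    Spacings grow quadratically: short delays are probed densely, long
    delays sparsely.
    """

    delays: np.ndarray
    n: int = field(init=False)
    t_max: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("DelayGrid needs at least two delays")
        if d[0] != 0.0:
            raise ValueError("DelayGrid must start at 0")
        diffs = np.diff(d)
        if not np.all(diffs > 0):
            raise ValueError("DelayGrid delays must be strictly increasing")
        if np.any(np.diff(diffs) < -1e-12 * d[-1]):
            raise ValueError("DelayGrid spacings must be non-decreasing")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "n", int(d.size))
        object.__setattr__(self, "t_max", float(d[-1]))

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.delays)


def build_delay_grid(n: int, t_max: float) -> DelayGrid:
    """Build a quadratically spaced delay grid on ``[0, t_max]``.

    tau_j = t_max * (j / (n - 1))**2 for j = 0..n-1, so successive spacings
    grow linearly with j and the grid concentrates candidate delays near 0.

    Parameters
    ----------
    n
        Number of delays (>= 2).
    t_max
        Largest delay in hours (> 0).
    """
    if not isinstance(n, (int, np.integer)) or n < 2:
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    if not t_max > 0:
        raise ValueError(f"t_max must be positive, got {t_max!r}")
    j = np.arange(n, dtype=float)
    return DelayGrid(t_max * (j / (n - 1)) ** 2)


def interpolate_linear(
    s: Series, query_times, *, extrapolate: str = "clamp"
) -> np.ndarray:
    """Piecewise-linear interpolation of ``s`` at ``query_times``.

    Queries outside the grid are clamped to the boundary knot value when
    ``extrapolate="clamp"`` (default) or extended along the boundary segment
    slope when ``extrapolate="linear"``.
    """
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    if q.size == 0:
        raise ValueError("query_times is empty")
    if not np.all(np.isfinite(q)):
        raise ValueError("query_times must be finite")
    t, v = s.grid.times, s.values
    out = np.interp(q, t, v)
    if extrapolate == "clamp":
        return out
    if extrapolate == "linear":
        lo, hi = q < t[0], q > t[-1]
        if lo.any():
            slope = (v[1] - v[0]) / (t[1] - t[0])
            out[lo] = v[0] + slope * (q[lo] - t[0])
        if hi.any():
            slope = (v[-1] - v[-2]) / (t[-1] - t[-2])
            out[hi] = v[-1] + slope * (q[hi] - t[-1])
        return out
    raise ValueError(f"unknown extrapolation policy {extrapolate!r}")


def align_timepoints(mrna_grid: TimeGrid, protein: Series) -> tuple[TimeGrid, Series]:
    """Align a protein trajectory onto an mRNA time grid.

    The paired grid keeps the mRNA time points that do not exceed the last
    protein measurement; protein values at mRNA-only times are linearly
    interpolated, and protein measurements beyond the mRNA horizon are
    dropped.

    Returns
    -------
    (TimeGrid, Series)
        The paired grid and the protein trajectory resampled onto it.

    Raises
    ------
    AlignmentError
        If the two grids share no overlapping time range or fewer than two
        mRNA points fall inside the protein range.
    """
    mt = mrna_grid.times
    pt = protein.grid.times
    if mt[0] > pt[-1] or mt[-1] < pt[0]:
        raise AlignmentError(
            f"mRNA grid [{mt[0]}, {mt[-1]}] h and protein grid "
            f"[{pt[0]}, {pt[-1]}] h do not overlap"
        )
    keep = mt <= pt[-1]
    if keep.sum() < 2:
        raise AlignmentError("fewer than two paired time points after alignment")
    paired = TimeGrid(mt[keep])
    values = interpolate_linear(protein, paired.times)
    return paired, Series(values, paired)
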