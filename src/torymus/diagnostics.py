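"""Summary diagnostics of simulated runs.

Pure functions of season series and spatial fields: threshold crossings and
time-to-suppression, density minima, pest implantation runs, invasion-front
radii and predator-prey cycle periods.  All crossings use strict inequalities
on end-of-season values, so reports are invariant under uniform shifts of the
year labels (only gaps and run lengths are compared across scenarios).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.signal import find_peaks

from .season_engine import SeasonSeries
from .spatial_engine import SpatialGrid

__all__ = [
    "SuppressionReport",
    "ImplantationReport",
    "time_to_suppression",
    "series_extrema",
    "implantation_runs",
    "front_radius_series",
    "cycle_periods",
]

#: parasitoid establishment trigger: the suppression clock starts when the
#: parasitoid egg density first exceeds this value
DEFAULT_TRIGGER = 0.1
#: nondimensional density equivalent to one insect per hectare
DEFAULT_THRESHOLD = 1e-7
#: "implantation" level: the pest counts as implanted near its maximum density
DEFAULT_IMPLANTATION_LEVEL = 0.9


@dataclass(frozen=True)
class SuppressionReport:
    """First-crossing summary of a season series.

    ``gap_seasons`` is the number of seasons from parasitoid establishment
    (first ``q > trigger``) to pest suppression (first ``v < threshold``);
    events that never occur are flagged undefined and the year fields hold
    ``None``.
    """

    year_q_exceeds: int | None
    year_v_below: int | None
    gap_seasons: int | None
    min_v: float
    year_min_v: int
    min_q: float
    year_min_q: int
    trigger: float
    threshold: float

    @property
    def q_exceeds_defined(self) -> bool:
        return self.year_q_exceeds is not None

    @property
    def v_below_defined(self) -> bool:
        return self.year_v_below is not None

    def to_dict(self) -> dict:
        return asdict(self)


def time_to_suppression(
    series: SeasonSeries,
    trigger: float = DEFAULT_TRIGGER,
    threshold: float = DEFAULT_THRESHOLD,
) -> SuppressionReport:
    """First crossings of the establishment trigger and extinction threshold.

    Both crossings are strict and evaluated on end-of-season values;
    ``gap_seasons = year_v_below - year_q_exceeds`` (may be zero or negative
    if the pest collapses before the trigger fires; undefined if either event
    never happens).
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    years = np.asarray(series.years)
    q = np.asarray(series.q_end)
    v = np.asarray(series.v_end)

    q_hits = np.nonzero(q > trigger)[0]
    v_hits = np.nonzero(v < threshold)[0]
    year_q = int(years[q_hits[0]]) if q_hits.size else None
    year_v = int(years[v_hits[0]]) if v_hits.size else None
    gap = year_v - year_q if (year_q is not None and year_v is not None) else None

    return SuppressionReport(
        year_q_exceeds=year_q,
        year_v_below=year_v,
        gap_seasons=gap,
        min_v=float(v.min()),
        year_min_v=int(years[int(np.argmin(v))]),
        min_q=float(q.min()),
        year_min_q=int(years[int(np.argmin(q))]),
        trigger=trigger,
        threshold=threshold,
    )


def series_extrema(
    series: SeasonSeries, window: tuple[int, int] | None = None
) -> tuple[float, int, float, int]:
    """Minima of end-of-season densities over a year window.

    ``window`` is an inclusive ``(first_year, last_year)`` pair in the
    series' own year labels; ``None`` means the whole series.  Returns
    ``(min_v, year_of_min_v, min_q, year_of_min_q)``.
    """
    years = np.asarray(series.years)
    if window is None:
        mask = np.ones(len(years), dtype=bool)
    else:
        lo, hi = window
        mask = (years >= lo) & (years <= hi)
    if not mask.any():
        raise ValueError(f"window {window} selects no seasons")
    v = np.asarray(series.v_end)[mask]
    q = np.asarray(series.q_end)[mask]
    yrs = years[mask]
    iv, iq = int(np.argmin(v)), int(np.argmin(q))
    return float(v[iv]), int(yrs[iv]), float(q[iq]), int(yrs[iq])


@dataclass(frozen=True)
class ImplantationReport:
    """Longest pest implantation run after the first local suppression.

    An implantation run is a stretch of consecutive seasons with the pest
    near its maximum density (``v > level``).  If the pest is never
    suppressed below ``level``, the run over the full series is reported with
    ``suppressed = False``.
    """

    longest_run: int
    level: float
    suppressed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def implantation_runs(
    series: SeasonSeries, level: float = DEFAULT_IMPLANTATION_LEVEL
) -> ImplantationReport:
    """Longest run of seasons with ``v > level`` after the first ``v < level``."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    v = np.asarray(series.v_end)
    below = np.nonzero(v < level)[0]

    def longest(mask: np.ndarray) -> int:
        best = run = 0
        for hit in mask:
            run = run + 1 if hit else 0
            best = max(best, run)
        return best

    if below.size == 0:
        return ImplantationReport(
            longest_run=longest(v > level), level=level, suppressed=False
        )
    after = v[below[0] + 1 :]
    return ImplantationReport(
        longest_run=longest(after > level), level=level, suppressed=True
    )


def front_radius_series(
    v_fields: np.ndarray,
    grid: SpatialGrid,
    release_point: tuple[float, float],
    iso: float = 0.5,
    n_angles: int = 64,
) -> np.ndarray:
    """Radius of the suppressed region around a release point, per year.

    For each year, rays are cast from the release point and the distance to
    the first sample where ``v`` rises through ``iso`` is recorded; the
    front radius is the median over rays that cross.  ``nan`` marks years
    with no front (release point not suppressed, or no crossing anywhere).

    This quantifies the radially expanding wave by which the parasitoid
    sweeps the pest outward from its release site.
    """
    if not grid.contains(release_point):
        raise ValueError(f"release point {release_point} outside the domain")
    v_fields = np.atleast_3d(v_fields.reshape((-1,) + grid.shape))
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    step = grid.h / 2.0
    max_r = float(np.hypot(grid.Lx, grid.Ly))
    radii_per_ray = np.arange(step, max_r, step)
    px, py = release_point

    out = np.full(v_fields.shape[0], np.nan)
    for t, v in enumerate(v_fields):
        if v[grid.nearest_index(release_point)] >= iso:
            continue  # no suppressed core, no front
        crossings = []
        for theta in angles:
            xs = px + radii_per_ray * np.cos(theta)
            ys = py + radii_per_ray * np.sin(theta)
            inside = (xs >= 0) & (xs <= grid.Lx) & (ys >= 0) & (ys <= grid.Ly)
            if not inside.any():
                continue
            ix = np.clip(np.round(xs[inside] / grid.h - 0.5).astype(int), 0, grid.nx - 1)
            iy = np.clip(np.round(ys[inside] / grid.h - 0.5).astype(int), 0, grid.ny - 1)
            samples = v[iy, ix]
            hit = np.nonzero(samples >= iso)[0]
            if hit.size:
                crossings.append(radii_per_ray[inside][hit[0]])
        if crossings:
            out[t] = float(np.median(crossings))
    return out


def cycle_periods(series: SeasonSeries, min_peak: float = 1e-2) -> np.ndarray:
    """Peak-to-peak intervals (years) of the pest density cycles.

    Peaks are local maxima of ``log10 v`` above ``min_peak``; returns the
    intervals between successive peaks (empty if fewer than two peaks).
    """
    if len(series) < 3:
        raise ValueError("series must have at least 3 seasons")
    v = np.asarray(series.v_end)
    logv = np.log10(np.clip(v, np.finfo(float).tiny, None))
    # plateau_size admits flat-topped peaks: v saturates at 1 for whole years
    peaks, _ = find_peaks(logv, plateau_size=(1, None))
    peaks = peaks[v[peaks] > min_peak]
    if peaks.size < 2:
        return np.array([], dtype=float)
    return np.diff(np.asarray(series.years)[peaks]).astype(float)
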