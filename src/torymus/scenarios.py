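"""Initial conditions and parasitoid release schedules.

The release experiments mirror the field strategies studied for Portuguese
chestnut woodlands: a single release near one corner of an infested square
domain, simultaneous releases on a regular lattice of stations, a second
timed release some years after the first, and strictly periodic releases.
All schedules are plain data (deterministic functions of their arguments)
and serialize losslessly to dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReleaseEvent",
    "ReleaseSchedule",
    "grid_release_layout",
    "make_release_schedule",
    "uniform_infestation_init",
]


@dataclass(frozen=True)
class ReleaseEvent:
    """One release: adults added to the parasitoid field at season start.

    ``footprint_radius`` of ``None`` means the single grid cell nearest each
    station; a positive radius covers every cell within it.
    """

    year: int
    stations: tuple[tuple[float, float], ...]
    amplitude: float = 1.0
    footprint_radius: float | None = None

    def __post_init__(self) -> None:
        if self.year < 1:
            raise ValueError(f"release year must be >= 1, got {self.year}")
        if self.amplitude <= 0.0:
            raise ValueError("release amplitude must be > 0")
        object.__setattr__(
            self, "stations", tuple((float(x), float(y)) for x, y in self.stations)
        )

    def to_dict(self) -> dict:
        return {
            "year": self.year,
            "stations": [list(s) for s in self.stations],
            "amplitude": self.amplitude,
            "footprint_radius": self.footprint_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReleaseEvent":
        return cls(
            year=int(d["year"]),
            stations=tuple(tuple(s) for s in d["stations"]),
            amplitude=float(d.get("amplitude", 1.0)),
            footprint_radius=d.get("footprint_radius"),
        )


@dataclass(frozen=True)
class ReleaseSchedule:
    """An ordered collection of release events."""

    events: tuple[ReleaseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.year))
        )

    def events_for_year(self, year: int) -> list[ReleaseEvent]:
        return [e for e in self.events if e.year == year]

    @property
    def years(self) -> list[int]:
        return [e.year for e in self.events]

    def to_dict(self) -> dict:
        return {"events": [e.to_dict() for e in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "ReleaseSchedule":
        return cls(events=tuple(ReleaseEvent.from_dict(e) for e in d["events"]))


def grid_release_layout(k: int, L: float) -> list[tuple[float, float]]:
    """Stations at the ``(k+1) x (k+1)`` vertices of a lattice spanning ``[0, L]^2``.

    ``k = 1`` places 4 stations at the corners; the station spacing is
    ``L / k`` (for a side of 4 units: spacings 4, 2, 4/3, 1 for k = 1..4).
    """
    if k < 1:
        raise ValueError(f"lattice order k must be >= 1, got {k}")
    if L <= 0.0:
        raise ValueError(f"domain side must be > 0, got {L}")
    ticks = np.linspace(0.0, L, k + 1)
    return [(float(x), float(y)) for y in ticks for x in ticks]


def make_release_schedule(
    mode: str,
    stations: list[tuple[float, float]],
    horizon: int,
    n_r: int | None = None,
    k_r: int | None = None,
    amplitude: float = 1.0,
    footprint_radius: float | None = None,
) -> ReleaseSchedule:
    """Build a release schedule.

    Modes
    -----
    ``initial-only``
        one event at year 1;
    ``timed``
        events at years 1 and ``n_r`` (a follow-up release);
    ``periodic``
        events at years 1, 1 + k_r, 1 + 2 k_r, ... up to ``horizon``.

    The same stations, amplitude and footprint are used for every event.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not stations:
        raise ValueError("at least one release station is required")

    def event(year: int) -> ReleaseEvent:
        return ReleaseEvent(
            year=year,
            stations=tuple(stations),
            amplitude=amplitude,
            footprint_radius=footprint_radius,
        )

    if mode == "initial-only":
        years = [1]
    elif mode == "timed":
        if n_r is None or n_r <= 1:
            raise ValueError("timed mode requires n_r > 1")
        years = [1, n_r]
    elif mode == "periodic":
        if k_r is None or k_r < 1:
            raise ValueError("periodic mode requires k_r >= 1")
        years = list(range(1, horizon + 1, k_r))
    else:
        raise ValueError(f"unknown release mode {mode!r}")
    return ReleaseSchedule(events=tuple(event(y) for y in years))


def uniform_infestation_init(grid=None, q0: float = 1e-9):
    """Initial conditions for a fully infested domain.

    Homogeneous runs (``grid`` is ``None``) start from gall-wasp egg density
    ``v = 1`` with a parasitoid seed ``q0`` (the default ``1e-9`` models the
    release of a few individuals per square kilometre); returns a
    :class:`~torymus.season_engine.SeasonInput`.

    Spatial runs start with ``v = 1`` at every node and an empty parasitoid
    field awaiting scheduled releases (``q0`` is ignored); returns a
    :class:`~torymus.spatial_engine.SpatialState`.
    """
    if q0 < 0.0:
        raise ValueError("q0 must be nonnegative")
    if grid is None:
        from .season_engine import SeasonInput

        return SeasonInput(v_prev=1.0, q_init_adults=q0)
    from .spatial_engine import SpatialState

    zeros = np.zeros(grid.shape)
    return SpatialState(
        p=zeros.copy(),
        q=zeros.copy(),
        u=zeros.copy(),
        v=np.ones(grid.shape),
        season=0,
        phase="initial",
    )
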