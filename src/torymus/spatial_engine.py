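"""Two-dimensional reaction-diffusion form of the season model.

Adult insects disperse; eggs do not.  Within each season the homogeneous
phase equations gain Laplacian terms on the adult fields only::

    dp/dt = delta * lap(p) - (1/tau) * (v_prev - q) * p
    dq/dt =             (E_t/tau) * (v_prev - q) * p
    du/dt = lap(u) - mu * (2 - v) * u + c(x, y)
    dv/dt =             E_d * mu * (1 - v) * u

on a rectangular domain with zero-flux (Neumann) boundaries: the woodland is
insulated, no insects enter or leave.  ``delta = D_t/D_d < 1`` encodes the
pest's superior dispersal, the mechanism behind its recolonization of areas
already swept by the parasitoid.

Discretization is method-of-lines on a regular cell-centered grid: 5-point
second-order Laplacian with ghost-cell reflection for the Neumann closure,
and the same adaptive Dormand-Prince 4(5) time integration as the
homogeneous engine.  Spatially uniform fields make the Laplacian vanish
identically, so uniform runs must reproduce the homogeneous engine exactly --
the primary correctness gate for this module, enforced in the test suite.

As in the homogeneous engine, the parasitoid phase carries the redundant
residual field ``s = v_prev - q`` so that the emergence rate
``c = v_{n-1}(x,y,1) - q_n(x,y,eta*tau)`` is computed without cancellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.integrate import solve_ivp

from .model_core import (
    InvalidParameterError,
    NondimensionalParameters,
    ThresholdSpec,
)
from .scenarios import ReleaseSchedule
from .season_engine import SeasonSeries, SolverError

__all__ = [
    "SpatialGrid",
    "SpatialState",
    "SpatialSeries",
    "discrete_laplacian",
    "apply_releases",
    "spatial_parasitoid_phase",
    "spatial_wasp_phase",
    "run_spatial_multi_year",
]

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-12

#: coarsest admissible grid spacing (resolution-adequacy bound)
MAX_SPACING = 0.1


@dataclass(frozen=True)
class SpatialGrid:
    """Regular cell-centered grid on ``[0, Lx] x [0, Ly]``.

    Cell centers sit at ``(i + 1/2) h``; the default spacing ``h = 0.05``
    nondimensional units is half the coarsest admissible value.
    """

    Lx: float
    Ly: float
    h: float = 0.05

    def __post_init__(self) -> None:
        if not (self.Lx > 0.0 and self.Ly > 0.0):
            raise InvalidParameterError("domain side lengths must be > 0")
        if not 0.0 < self.h <= MAX_SPACING:
            raise InvalidParameterError(
                f"grid spacing h must be in (0, {MAX_SPACING}], got {self.h}"
            )
        for L, n in ((self.Lx, self.nx), (self.Ly, self.ny)):
            if abs(n * self.h - L) > self.h:
                raise InvalidParameterError(
                    f"domain side {L} is not spanned by a whole number of cells of {self.h}"
                )

    @property
    def nx(self) -> int:
        return int(round(self.Lx / self.h))

    @property
    def ny(self) -> int:
        return int(round(self.Ly / self.h))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.h

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.h

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def contains(self, point: tuple[float, float]) -> bool:
        px, py = point
        return 0.0 <= px <= self.Lx and 0.0 <= py <= self.Ly

    def nearest_index(self, point: tuple[float, float]) -> tuple[int, int]:
        """Map an ``(x, y)`` coordinate to the nearest cell index ``(iy, ix)``."""
        if not self.contains(point):
            raise ValueError(f"point {point} lies outside the domain")
        px, py = point
        ix = min(int(np.argmin(np.abs(self.x - px))), self.nx - 1)
        iy = min(int(np.argmin(np.abs(self.y - py))), self.ny - 1)
        return iy, ix


@dataclass
class SpatialState:
    """Gridded density fields of one season/phase."""

    p: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    season: int = 0
    phase: str = "end-of-season"

    def validate(self, grid: SpatialGrid) -> None:
        for name in ("p", "q", "u", "v"):
            arr = getattr(self, name)
            if arr.shape != grid.shape:
                raise ValueError(
                    f"field {name} has shape {arr.shape}, expected {grid.shape}"
                )
            if np.any(arr < 0.0):
                raise ValueError(f"field {name} has negative entries")


def discrete_laplacian(fld: np.ndarray, grid: SpatialGrid) -> np.ndarray:
    """5-point Laplacian with zero-flux Neumann closure via ghost reflection.

    A linear operator; constant fields map to exactly zero and the grid sum
    of the output vanishes identically (no flux through the boundary).
    """
    if fld.shape != grid.shape:
        raise ValueError(f"field shape {fld.shape} does not match grid {grid.shape}")
    fp = np.pad(fld, 1, mode="edge")
    return (
        fp[:-2, 1:-1] + fp[2:, 1:-1] + fp[1:-1, :-2] + fp[1:-1, 2:] - 4.0 * fld
    ) / (grid.h * grid.h)


def apply_releases(
    p: np.ndarray,
    grid: SpatialGrid,
    stations: list[tuple[float, float]],
    amplitude: float = 1.0,
    footprint_radius: float | None = None,
) -> float:
    """Add parasitoid adults at release stations, in place.

    Each station sets ``p`` additively to at most 1.0 on its footprint: the
    single nearest cell by default, or every cell within ``footprint_radius``
    of the station.  Returns the released amount (density times area).
    """
    before = p.sum()
    if footprint_radius:
        X, Y = np.meshgrid(grid.x, grid.y)
        for sx, sy in stations:
            if not grid.contains((sx, sy)):
                raise ValueError(f"release station {(sx, sy)} outside the domain")
            mask = (X - sx) ** 2 + (Y - sy) ** 2 <= footprint_radius**2
            if not mask.any():  # footprint smaller than a cell
                mask = np.zeros(grid.shape, dtype=bool)
                mask[grid.nearest_index((sx, sy))] = True
            p[mask] = np.minimum(p[mask] + amplitude, 1.0)
    else:
        for station in stations:
            iy, ix = grid.nearest_index(station)
            p[iy, ix] = min(p[iy, ix] + amplitude, 1.0)
    return float((p.sum() - before) * grid.cell_area)


def _solve_fields(rhs, t_end, y0, rtol, atol, context):
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="RK45", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SolverError(f"{context}: {sol.message}")
    return sol.y[:, -1]


def spatial_parasitoid_phase(
    p0: np.ndarray,
    v_prev: np.ndarray,
    grid: SpatialGrid,
    params: NondimensionalParameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the parasitoid phase fields; returns ``(p, q, s)`` at the end."""
    n = grid.ny * grid.nx
    inv_tau = 1.0 / params.tau
    E_t = params.E_t
    delta = params.delta

    def rhs(t, y):
        p = y[:n].reshape(grid.shape)
        s = y[2 * n :]
        r = inv_tau * s * y[:n]
        dp = (delta * discrete_laplacian(p, grid)).ravel() - r
        return np.concatenate([dp, E_t * r, -E_t * r])

    y0 = np.concatenate([p0.ravel(), np.zeros(n), v_prev.ravel()])
    y_end = _solve_fields(
        rhs, params.parasitoid_phase_length, y0, rtol, atol, "spatial parasitoid phase"
    )
    p_end = np.clip(y_end[:n].reshape(grid.shape), 0.0, None)
    q_end = np.clip(y_end[n : 2 * n].reshape(grid.shape), 0.0, v_prev)
    s_end = np.clip(y_end[2 * n :].reshape(grid.shape), 0.0, None)
    return p_end, q_end, s_end


def spatial_wasp_phase(
    emergence: np.ndarray,
    grid: SpatialGrid,
    params: NondimensionalParameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the gall-wasp phase fields; returns ``(u, v)`` at the end."""
    n = grid.ny * grid.nx
    mu = params.mu
    E_d = params.E_d
    c = np.clip(emergence, 0.0, None).ravel()

    def rhs(t, y):
        u = y[:n]
        v = y[n:]
        du = (
            discrete_laplacian(u.reshape(grid.shape), grid).ravel()
            - mu * (2.0 - v) * u
            + c
        )
        return np.concatenate([du, E_d * mu * (1.0 - v) * u])

    y_end = _solve_fields(
        rhs, params.wasp_phase_length, np.zeros(2 * n), rtol, atol, "spatial gall-wasp phase"
    )
    u_end = np.clip(y_end[:n].reshape(grid.shape), 0.0, None)
    v_end = np.clip(y_end[n:].reshape(grid.shape), 0.0, 1.0)
    return u_end, v_end


@dataclass
class SpatialSeries:
    """End-of-season fields for every simulated year."""

    years: np.ndarray
    p: np.ndarray  # (year, y, x)
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    grid: SpatialGrid
    params: NondimensionalParameters | None = None
    metadata: dict = field(default_factory=dict)

    def to_dataset(self) -> xr.Dataset:
        coords = {"year": self.years, "y": self.grid.y, "x": self.grid.x}
        attrs = {"Lx": self.grid.Lx, "Ly": self.grid.Ly, "h": self.grid.h}
        if self.params is not None:
            attrs.update(self.params.to_dict())
        return xr.Dataset(
            {
                name: (("year", "y", "x"), getattr(self, name))
                for name in ("p", "q", "u", "v")
            },
            coords=coords,
            attrs=attrs,
        )


def run_spatial_multi_year(
    grid: SpatialGrid,
    init: SpatialState,
    schedule: ReleaseSchedule | None,
    params: NondimensionalParameters,
    n_years: int,
    threshold: ThresholdSpec | None = None,
    probes: list[tuple[float, float]] | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[SpatialSeries, list[SeasonSeries]]:
    """Iterate the spatial season map for ``n_years`` years.

    Scheduled releases are applied to the adult parasitoid field ``p`` at the
    start of their season.  End-of-season fields are stored per year, and a
    :class:`~torymus.season_engine.SeasonSeries` is extracted at the grid
    cell nearest each probe coordinate.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    init.validate(grid)
    probes = list(probes or [])
    probe_idx = [grid.nearest_index(pt) for pt in probes]
    if schedule is not None:
        for event in schedule.events:
            if event.year > n_years:
                raise ValueError(
                    f"release scheduled at year {event.year} beyond horizon {n_years}"
                )
            for station in event.stations:
                if not grid.contains(station):
                    raise ValueError(f"release station {station} outside the domain")

    shape = (n_years,) + grid.shape
    fields = {name: np.empty(shape) for name in ("p", "q", "u", "v")}
    p_next = init.p.copy()
    v_prev = init.v.copy()

    for i in range(n_years):
        year = i + 1
        if schedule is not None:
            for event in schedule.events_for_year(year):
                released = apply_releases(
                    p_next,
                    grid,
                    event.stations,
                    amplitude=event.amplitude,
                    footprint_radius=event.footprint_radius,
                )
                logger.info(
                    "year %d: released %.4g (density x area) at %d station(s)",
                    year,
                    released,
                    len(event.stations),
                )
        try:
            p_end, q_end, s_end = spatial_parasitoid_phase(
                p_next, v_prev, grid, params, rtol=rtol, atol=atol
            )
            u_end, v_end = spatial_wasp_phase(
                s_end, grid, params, rtol=rtol, atol=atol
            )
        except SolverError as err:
            raise SolverError(f"season {year}: {err}") from err
        fields["p"][i] = p_end
        fields["q"][i] = q_end
        fields["u"][i] = u_end
        fields["v"][i] = v_end
        logger.debug(
            "season %d: min v=%.3e, max q=%.3e", year, v_end.min(), q_end.max()
        )
        p_next = q_end.copy()
        v_prev = v_end

    years = np.arange(1, n_years + 1)
    series = SpatialSeries(
        years=years,
        p=fields["p"],
        q=fields["q"],
        u=fields["u"],
        v=fields["v"],
        grid=grid,
        params=params,
        metadata={"rtol": rtol, "atol": atol},
    )
    probe_series = [
        SeasonSeries(
            years=years,
            v_end=fields["v"][:, iy, ix].copy(),
            q_end=fields["q"][:, iy, ix].copy(),
            p_end=fields["p"][:, iy, ix].copy(),
            u_end=fields["u"][:, iy, ix].copy(),
            clamped=np.zeros(n_years, dtype=bool),
            params=params,
            metadata={"probe": probes[k], "cell": (iy, ix)},
        )
        for k, (iy, ix) in enumerate(probe_idx)
    ]
    return series, probe_series
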