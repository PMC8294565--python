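"""Spatially homogeneous season map: within-year ODEs and the multi-year loop.

Each year ``n`` is integrated in two sequential phases, in nondimensional
time ``t`` (units of the gall-wasp season length ``T_d``):

1. *Parasitoid phase*, ``t in [0, eta*tau]``.  Adult parasitoid females
   ``p_n`` attack the gall-wasp larvae that survived the winter, laying eggs
   ``q_n`` in them::

       dp/dt = -(1/tau) * (v_prev - q) * p
       dq/dt =  (E_t/tau) * (v_prev - q) * p,      q(0) = 0

   where ``v_prev = v_{n-1}(1)`` is last season's end-of-season gall-wasp egg
   density.  ``p_n(0) = q_{n-1}(eta*tau)``: the parasitoid overwintering
   survival is absorbed in the scaling of ``p``.

2. *Gall-wasp phase*, ``t in [0, 1]``.  Adults ``u_n`` emerge from the
   unparasitized larvae at constant rate ``c = v_prev - q_n(eta*tau)`` and
   lay eggs ``v_n`` in the remaining bud capacity::

       du/dt = -mu * (2 - v) * u + c
       dv/dt =  E_d * mu * (1 - v) * u,            u(0) = v(0) = 0

Numerical formulation
---------------------
The emergence rate ``c`` is the *residual* of a near-total parasitism and can
be exponentially small (below 1e-50 in multi-decade runs), so forming it as a
float difference ``v_prev - q_end`` would be limited by catastrophic
cancellation regardless of solver tolerances.  The parasitoid phase is
therefore integrated in the redundant variables ``(p, q, s)`` with
``s = v_prev - q`` carried as its own unknown (``ds/dt = -dq/dt``): ``q`` is
accurate when small (early seasons), ``s`` is accurate when small (crash
seasons), and ``q + s = v_prev`` holds to solver tolerance.  The phase is a
logistic system with a closed form, which the test suite uses as an
independent oracle.

Integration uses the adaptive Dormand-Prince 4(5) pair (scipy ``RK45``) with
``rtol = 1e-8`` and a zero absolute floor, so densities spanning dozens of
decades stay resolved in relative terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import NondimensionalParameters, ThresholdSpec

__all__ = [
    "SolverError",
    "SeasonInput",
    "PhaseTrajectory",
    "ParasitoidPhaseResult",
    "WaspPhaseResult",
    "SeasonResult",
    "SeasonSeries",
    "parasitoid_phase",
    "wasp_phase",
    "run_multi_year",
]

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 0.0


class SolverError(RuntimeError):
    """The adaptive integrator failed (e.g. step-size underflow)."""


@dataclass(frozen=True)
class SeasonInput:
    """Initial conditions of a season.

    ``v_prev`` is the end-of-previous-season gall-wasp egg density
    ``v_{n-1}(1)`` and ``q_init_adults`` is ``p_n(0) = q_{n-1}(eta*tau)``.
    """

    v_prev: float
    q_init_adults: float

    def __post_init__(self) -> None:
        if self.v_prev < 0.0 or self.q_init_adults < 0.0:
            raise ValueError("season initial densities must be nonnegative")
        if self.v_prev > 1.0 + 1e-12:
            raise ValueError(f"v_prev must be <= 1, got {self.v_prev}")


@dataclass(frozen=True)
class PhaseTrajectory:
    """Accepted solver steps of one within-season phase."""

    t: np.ndarray
    fields: dict[str, np.ndarray]


@dataclass(frozen=True)
class ParasitoidPhaseResult:
    p_end: float
    q_end: float
    #: well-conditioned emergence residual s = v_prev - q at the phase end
    s_end: float
    trajectory: PhaseTrajectory | None = None


@dataclass(frozen=True)
class WaspPhaseResult:
    u_end: float
    v_end: float
    trajectory: PhaseTrajectory | None = None


@dataclass(frozen=True)
class SeasonResult:
    """End-of-season densities of one year."""

    p_end: float
    q_end: float
    u_end: float
    v_end: float
    parasitoid: ParasitoidPhaseResult | None = None
    wasp: WaspPhaseResult | None = None


def _solve(rhs, t_span, y0, rtol, atol, context):
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        first_step=t_span[1] * 1e-4,
    )
    if not sol.success:
        raise SolverError(f"{context}: {sol.message}")
    return sol


def parasitoid_phase(
    p0: float,
    v_prev: float,
    params: NondimensionalParameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    keep_trajectory: bool = False,
) -> ParasitoidPhaseResult:
    """Integrate the parasitoid phase over ``t in [0, eta*tau]``.

    Returns the end-of-phase adult density ``p_end``, the laid-egg density
    ``q_end`` (monotonically nondecreasing, ``q_end <= v_prev``) and the
    residual ``s_end = v_prev - q_end`` free of cancellation error.
    """
    if p0 < 0.0 or v_prev < 0.0:
        raise ValueError("p0 and v_prev must be nonnegative")
    t_end = params.parasitoid_phase_length
    if p0 == 0.0 or v_prev == 0.0:
        # No adults, or no hosts: both derivatives vanish identically.
        traj = (
            PhaseTrajectory(
                t=np.array([0.0, t_end]),
                fields={
                    "p": np.array([p0, p0]),
                    "q": np.zeros(2),
                    "s": np.full(2, v_prev),
                },
            )
            if keep_trajectory
            else None
        )
        return ParasitoidPhaseResult(p_end=p0, q_end=0.0, s_end=v_prev, trajectory=traj)

    inv_tau = 1.0 / params.tau
    E_t = params.E_t

    def rhs(t, y):
        p, q, s = y
        r = inv_tau * s * p
        return (-r, E_t * r, -E_t * r)

    sol = _solve(rhs, (0.0, t_end), [p0, 0.0, v_prev], rtol, atol, "parasitoid phase")
    p_end, q_end, s_end = sol.y[:, -1]
    q_end = min(max(q_end, 0.0), v_prev)
    s_end = max(s_end, 0.0)
    traj = (
        PhaseTrajectory(t=sol.t, fields={"p": sol.y[0], "q": sol.y[1], "s": sol.y[2]})
        if keep_trajectory
        else None
    )
    return ParasitoidPhaseResult(p_end=p_end, q_end=q_end, s_end=s_end, trajectory=traj)


def wasp_phase(
    v_prev: float,
    q_end: float,
    params: NondimensionalParameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    keep_trajectory: bool = False,
    emergence: float | None = None,
) -> WaspPhaseResult:
    """Integrate the gall-wasp phase over ``t in [0, 1]``.

    The constant emergence rate is ``c = v_prev - q_end`` (clipped at zero to
    absorb solver overshoot).  ``emergence`` overrides the difference with a
    well-conditioned residual, as supplied by :func:`parasitoid_phase`; the
    multi-year loop always passes it.
    """
    if v_prev < 0.0 or q_end < 0.0:
        raise ValueError("v_prev and q_end must be nonnegative")
    c = emergence if emergence is not None else v_prev - q_end
    c = max(c, 0.0)
    t_end = params.wasp_phase_length
    if c == 0.0:
        # Nothing emerges: the empty state is absorbing.
        traj = (
            PhaseTrajectory(
                t=np.array([0.0, t_end]),
                fields={"u": np.zeros(2), "v": np.zeros(2)},
            )
            if keep_trajectory
            else None
        )
        return WaspPhaseResult(u_end=0.0, v_end=0.0, trajectory=traj)

    mu = params.mu
    E_d = params.E_d

    def rhs(t, y):
        u, v = y
        return (-mu * (2.0 - v) * u + c, E_d * mu * (1.0 - v) * u)

    sol = _solve(rhs, (0.0, t_end), [0.0, 0.0], rtol, atol, "gall-wasp phase")
    u_end, v_end = sol.y[:, -1]
    v_end = min(max(v_end, 0.0), 1.0)
    u_end = max(u_end, 0.0)
    traj = (
        PhaseTrajectory(t=sol.t, fields={"u": sol.y[0], "v": sol.y[1]})
        if keep_trajectory
        else None
    )
    return WaspPhaseResult(u_end=u_end, v_end=v_end, trajectory=traj)


@dataclass
class SeasonSeries:
    """Per-year end-of-season densities of a homogeneous multi-year run."""

    years: np.ndarray
    v_end: np.ndarray
    q_end: np.ndarray
    p_end: np.ndarray
    u_end: np.ndarray
    clamped: np.ndarray
    params: NondimensionalParameters | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("v_end", "q_end", "p_end", "u_end", "clamped"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length of {name} does not match years")
        if np.any(self.v_end < 0.0) or np.any(self.q_end < 0.0):
            raise ValueError("densities must be nonnegative")

    def __len__(self) -> int:
        return len(self.years)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "v_end": self.v_end,
                "q_end": self.q_end,
                "p_end": self.p_end,
                "u_end": self.u_end,
                "clamped": self.clamped,
            }
        )


def run_multi_year(
    init: SeasonInput,
    params: NondimensionalParameters,
    n_years: int,
    threshold: ThresholdSpec | None = None,
    clamp: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SeasonSeries:
    """Iterate the season map for ``n_years`` years.

    Year ``n`` runs the parasitoid phase with ``p_n(0) = q_{n-1}(eta*tau)``
    and ``v_prev = v_{n-1}(1)``, then the gall-wasp phase with emergence
    ``v_{n-1}(1) - q_n(eta*tau)``.  With ``clamp`` on, end-of-season
    densities below ``threshold.effective_threshold`` are set to zero and the
    season flagged (local extinction); by default densities are reported
    unclamped and threshold crossings are left to the diagnostics module.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if clamp and threshold is None:
        raise ValueError("clamping requires a ThresholdSpec")

    v_prev = init.v_prev
    p0 = init.q_init_adults
    out = {name: np.empty(n_years) for name in ("v_end", "q_end", "p_end", "u_end")}
    clamped = np.zeros(n_years, dtype=bool)

    for i in range(n_years):
        year = i + 1
        try:
            par = parasitoid_phase(p0, v_prev, params, rtol=rtol, atol=atol)
            wasp = wasp_phase(
                v_prev, par.q_end, params, rtol=rtol, atol=atol, emergence=par.s_end
            )
        except SolverError as err:
            raise SolverError(f"season {year}: {err}") from err
        v_end, q_end = wasp.v_end, par.q_end
        if clamp:
            thr = threshold.effective_threshold
            if 0.0 < v_end < thr:
                v_end = 0.0
                clamped[i] = True
            if 0.0 < q_end < thr:
                q_end = 0.0
                clamped[i] = True
        out["v_end"][i] = v_end
        out["q_end"][i] = q_end
        out["p_end"][i] = par.p_end
        out["u_end"][i] = wasp.u_end
        logger.debug(
            "season %d: v_end=%.3e q_end=%.3e", year, v_end, q_end
        )
        v_prev, p0 = v_end, q_end

    return SeasonSeries(
        years=np.arange(1, n_years + 1),
        v_end=out["v_end"],
        q_end=out["q_end"],
        p_end=out["p_end"],
        u_end=out["u_end"],
        clamped=clamped,
        params=params,
        metadata={"rtol": rtol, "atol": atol, "clamp": clamp},
    )
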