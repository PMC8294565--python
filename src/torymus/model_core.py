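"""Model constants, nondimensionalization and extinction-threshold arithmetic.

The simulator describes the interaction between the Asian chestnut gall wasp
*Dryocosmus kuriphilus* (the pest) and its host-specific parasitoid *Torymus
sinensis* (the biocontrol agent).  Both insects are univoltine: each year the
within-season dynamics of adults and eggs are integrated as ordinary (or
reaction-diffusion) differential equations, and the end-of-season egg
densities seed the next year's initial conditions.

This module holds the dimensional biological constants, the derived
nondimensional parameter group used by the season engines, and the
egg-capacity / survival-threshold arithmetic that converts nondimensional
densities back into "insects per hectare" terms.

Nondimensional conventions
--------------------------
Densities are scaled by the habitat egg capacity ``V_max = M * beta_max``
(eggs per hectare), time by the gall-wasp egg-deposition season length
``T_d``, and length by ``sqrt(D_d * T_d)``.  The derived constants are

* ``mu = T_d / a`` -- season length over adult lifespan of the gall wasp,
* ``E_d = eta * N_d`` -- effective fecundity of the gall wasp,
* ``E_t = gamma * N_t`` -- effective fecundity of the parasitoid,
* ``tau = T_t / (eta * T_d)`` -- scaled parasitoid season length; when the two
  egg-deposition seasons are taken equal (``T_t = T_d``) this simplifies to
  ``tau = 1 / eta``, and the parasitoid phase spans ``eta * tau = 1``
  nondimensional time units,
* ``delta = D_t / D_d`` -- parasitoid-to-pest diffusivity ratio (< 1: the
  pest disperses faster).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

__all__ = [
    "InvalidParameterError",
    "DimensionalParameters",
    "NondimensionalParameters",
    "ThresholdSpec",
    "nondimensionalize",
    "egg_capacity_and_threshold",
]


class InvalidParameterError(ValueError):
    """A parameter value violates one of the model invariants."""


# Default parameter set for Portuguese chestnut orchards.  The gall-wasp
# overwintering survival rate eta is deliberately *not* defaulted: it is the
# most uncertain parameter and must be chosen by the user (field estimates
# bound it below 0.9; the studied values are 0.65, 0.75 and 0.85).
PORTUGAL_DEFAULTS = {
    "N_d": 150.0,
    "N_t": 71.0,
    "T_d": 40.0,
    "a": 4.0,
    "gamma": 0.47,
    "M": 5.0,
    "beta_max": 2.0e6,
    "D_d": 0.889,
    "D_t": 0.016,
}


@dataclass(frozen=True)
class DimensionalParameters:
    """Biological and physical constants of the host-parasitoid system.

    Parameters
    ----------
    eta:
        Gall-wasp overwintering survival rate: fraction of eggs laid in
        season ``n-1`` that emerge as adult females in season ``n``.
        In ``(0, 1]`` (thelytokous, all-female reproduction).
    N_d, N_t:
        Maximum eggs laid per female over its life (gall wasp, parasitoid).
    T_d:
        Gall-wasp egg-deposition season length, days.
    T_t:
        Parasitoid adult lifespan / season length, days.  ``None`` selects
        the equal-season simplification ``T_t = T_d`` (hence ``tau = 1/eta``).
    a:
        Gall-wasp adult lifespan, days (``a < T_d``).
    gamma:
        Parasitoid overwintering survival rate, in ``(0, 0.5)``: sexual
        reproduction caps the female fraction of emerging adults below 1/2.
    M:
        Maximum eggs per chestnut bud.
    beta_max:
        Bud density, buds per hectare.
    D_d, D_t:
        Diffusion coefficients (km^2/day) of gall-wasp and parasitoid adults.
    """

    eta: float
    N_d: float = PORTUGAL_DEFAULTS["N_d"]
    N_t: float = PORTUGAL_DEFAULTS["N_t"]
    T_d: float = PORTUGAL_DEFAULTS["T_d"]
    a: float = PORTUGAL_DEFAULTS["a"]
    gamma: float = PORTUGAL_DEFAULTS["gamma"]
    M: float = PORTUGAL_DEFAULTS["M"]
    beta_max: float = PORTUGAL_DEFAULTS["beta_max"]
    D_d: float = PORTUGAL_DEFAULTS["D_d"]
    D_t: float = PORTUGAL_DEFAULTS["D_t"]
    T_t: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise InvalidParameterError(
                f"eta (gall-wasp overwintering survival) must be in (0, 1], got {self.eta}"
            )
        if not 0.0 < self.gamma < 0.5:
            raise InvalidParameterError(
                f"gamma (parasitoid overwintering survival) must be in (0, 0.5); "
                f"sexual reproduction bounds it below 0.5, got {self.gamma}"
            )
        for name in ("N_d", "N_t", "T_d", "a", "M", "beta_max", "D_d", "D_t"):
            value = getattr(self, name)
            if not value > 0.0:
                raise InvalidParameterError(f"{name} must be > 0, got {value}")
        if self.T_t is not None and not self.T_t > 0.0:
            raise InvalidParameterError(f"T_t must be > 0, got {self.T_t}")
        if not self.a < self.T_d:
            raise InvalidParameterError(
                f"adult lifespan a={self.a} must be shorter than the season T_d={self.T_d}"
            )

    # -- derived dimensional rates (not stored) ---------------------------

    @property
    def effective_T_t(self) -> float:
        """Parasitoid season length, with the equal-season default."""
        return self.T_d if self.T_t is None else self.T_t

    @property
    def r_d(self) -> float:
        """Gall-wasp laying rate under ideal conditions, eggs/day."""
        return self.N_d / self.a

    @property
    def r_t(self) -> float:
        """Parasitoid laying rate under ideal conditions, eggs/day."""
        return self.N_t / self.effective_T_t

    @property
    def V_max(self) -> float:
        """Habitat egg capacity, eggs per hectare."""
        return self.M * self.beta_max

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NondimensionalParameters:
    """Derived constants of the nondimensional season model."""

    mu: float
    tau: float
    E_d: float
    E_t: float
    delta: float
    parasitoid_phase_length: float
    length_unit_km: float
    wasp_phase_length: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "mu",
            "tau",
            "E_d",
            "E_t",
            "delta",
            "parasitoid_phase_length",
            "length_unit_km",
            "wasp_phase_length",
        ):
            value = getattr(self, name)
            if not value > 0.0:
                raise InvalidParameterError(f"{name} must be > 0, got {value}")

    def to_dict(self) -> dict:
        return asdict(self)


def nondimensionalize(dim: DimensionalParameters) -> NondimensionalParameters:
    """Derive the nondimensional parameter group from dimensional constants.

    Pure, deterministic function of its argument.  ``tau`` uses the exact
    definition ``T_t / (eta * T_d)`` when ``T_t`` is supplied, and the
    equal-season simplification ``1 / eta`` otherwise; in the latter case the
    parasitoid phase length ``eta * tau`` equals 1.
    """
    dim.validate()
    if dim.T_t is None:
        tau = 1.0 / dim.eta
    else:
        tau = dim.T_t / (dim.eta * dim.T_d)
    return NondimensionalParameters(
        mu=dim.T_d / dim.a,
        tau=tau,
        E_d=dim.eta * dim.N_d,
        E_t=dim.gamma * dim.N_t,
        delta=dim.D_t / dim.D_d,
        parasitoid_phase_length=dim.eta * tau,
        length_unit_km=math.sqrt(dim.D_d * dim.T_d),
    )


@dataclass(frozen=True)
class ThresholdSpec:
    """Egg capacity and the matching local-extinction threshold.

    A nondimensional density of ``1 / V_max`` corresponds to one insect per
    hectare; below that the population is deemed locally extinct.  For a
    monitored woodland of ``area_ha`` hectares the threshold scales down to
    ``1 / (V_max * area_ha)`` (one insect in the whole area).
    """

    V_max: float
    survival_threshold: float
    area_ha: float
    effective_threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


def egg_capacity_and_threshold(
    M: float, beta_max: float, area_ha: float = 1.0
) -> ThresholdSpec:
    """Compute ``V_max = M * beta_max`` and the survival threshold.

    Parameters
    ----------
    M:
        Maximum eggs per bud.
    beta_max:
        Bud density, buds per hectare.
    area_ha:
        Monitored area in hectares (default one hectare).
    """
    for name, value in (("M", M), ("beta_max", beta_max), ("area_ha", area_ha)):
        if not value > 0.0:
            raise InvalidParameterError(f"{name} must be > 0, got {value}")
    v_max = M * beta_max
    survival_threshold = 1.0 / v_max
    return ThresholdSpec(
        V_max=v_max,
        survival_threshold=survival_threshold,
        area_ha=area_ha,
        effective_threshold=survival_threshold / area_ha,
    )
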