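"""Independent reference implementations used only by the tests.

These deliberately avoid the package's solver path: a fixed-step classical
RK4 integrator applied to the *direct* (p, q) / (u, v) equations, and the
closed-form solution of the parasitoid phase (the transformed system
p' = -(1/tau) s p, s' = -(E_t/tau) s p is logistic in p).
"""

from __future__ import annotations

import math


def rk4_parasitoid(
    p0: float, v_prev: float, E_t: float, tau: float, t_end: float, dt: float = 1e-5
) -> tuple[float, float]:
    """Fixed-step RK4 on dp/dt = -(1/tau)(v_prev - q)p, dq/dt = E_t/tau (v_prev - q)p."""
    n = int(round(t_end / dt))
    inv_tau = 1.0 / tau
    p, q = p0, 0.0

    def f(p: float, q: float) -> tuple[float, float]:
        r = inv_tau * (v_prev - q) * p
        return -r, E_t * r

    for _ in range(n):
        k1p, k1q = f(p, q)
        k2p, k2q = f(p + 0.5 * dt * k1p, q + 0.5 * dt * k1q)
        k3p, k3q = f(p + 0.5 * dt * k2p, q + 0.5 * dt * k2q)
        k4p, k4q = f(p + dt * k3p, q + dt * k3q)
        p += dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        q += dt / 6.0 * (k1q + 2.0 * k2q + 2.0 * k3q + k4q)
    return p, q


def rk4_wasp(
    c: float, E_d: float, mu: float, t_end: float = 1.0, dt: float = 1e-5
) -> tuple[float, float]:
    """Fixed-step RK4 on du/dt = -mu(2 - v)u + c, dv/dt = E_d mu (1 - v)u."""
    n = int(round(t_end / dt))
    u, v = 0.0, 0.0

    def f(u: float, v: float) -> tuple[float, float]:
        return -mu * (2.0 - v) * u + c, E_d * mu * (1.0 - v) * u

    for _ in range(n):
        k1u, k1v = f(u, v)
        k2u, k2v = f(u + 0.5 * dt * k1u, v + 0.5 * dt * k1v)
        k3u, k3v = f(u + 0.5 * dt * k2u, v + 0.5 * dt * k2v)
        k4u, k4v = f(u + dt * k3u, v + dt * k3v)
        u += dt / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        v += dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    return u, v


def parasitoid_closed_form(
    p0: float, v_prev: float, E_t: float, tau: float, t_end: float
) -> tuple[float, float, float]:
    """Exact (p, q, s) at t_end for the parasitoid phase.

    With A = v_prev - E_t p0 the adult density obeys a logistic equation,
    giving p(t) = A p0 / (v_prev e^{A t/tau} - E_t p0); the laid-egg density
    and the residual follow in cancellation-free forms::

        q(t) = E_t p0 v_prev expm1(A t/tau) / (v_prev e^{A t/tau} - E_t p0)
        s(t) = A v_prev  exp(A t/tau)        / (v_prev e^{A t/tau} - E_t p0)
    """
    if p0 == 0.0 or v_prev == 0.0:
        return p0, 0.0, v_prev
    A = v_prev - E_t * p0
    x = A * t_end / tau
    if A == 0.0:
        p = p0 / (1.0 + E_t * p0 * t_end / tau)
        return p, E_t * (p0 - p), E_t * p
    denom = v_prev * math.exp(x) - E_t * p0
    p = A * p0 / denom
    q = E_t * p0 * v_prev * math.expm1(x) / denom
    s = A * v_prev * math.exp(x) / denom
    return p, q, s


def wasp_linear_limit(c: float, mu: float, t: float) -> float:
    """Closed-form u(t) = (c / 2 mu)(1 - e^{-2 mu t}) in the E_d -> 0 limit."""
    return c / (2.0 * mu) * -math.expm1(-2.0 * mu * t)
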