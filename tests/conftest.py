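from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import torymus as tm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_eta065() -> tm.NondimensionalParameters:
    return tm.nondimensionalize(tm.DimensionalParameters(eta=0.65))


@pytest.fixture(scope="session")
def params_eta085() -> tm.NondimensionalParameters:
    return tm.nondimensionalize(tm.DimensionalParameters(eta=0.85))


@pytest.fixture(scope="session")
def threshold() -> tm.ThresholdSpec:
    return tm.egg_capacity_and_threshold(5.0, 2.0e6)


@pytest.fixture(scope="session")
def homogeneous_300yr():
    """300-year homogeneous runs keyed by eta (computed once, on demand)."""
    cache: dict[float, tm.SeasonSeries] = {}

    def run(eta: float) -> tm.SeasonSeries:
        if eta not in cache:
            params = tm.nondimensionalize(tm.DimensionalParameters(eta=eta))
            cache[eta] = tm.run_multi_year(
                tm.uniform_infestation_init(), params, 300
            )
        return cache[eta]

    return run


@pytest.fixture(scope="session")
def corner_release_run(params_eta065):
    """The single corner-release experiment: 4x4 domain, h=0.05, 35 years."""
    grid = tm.SpatialGrid(4.0, 4.0, 0.05)
    state = tm.uniform_infestation_init(grid)
    schedule = tm.make_release_schedule("initial-only", [(0.0, 0.0)], horizon=35)
    spatial, probes = tm.run_spatial_multi_year(
        grid, state, schedule, params_eta065, 35, probes=[(1.0, 1.0)]
    )
    return grid, spatial, probes[0]


@pytest.fixture(scope="session")
def lattice_release_runs(params_eta065):
    """Simultaneous lattice releases (k = 1..4 on demand): probe series at (1, 1)."""
    cache: dict[int, tm.SeasonSeries] = {}
    grid = tm.SpatialGrid(4.0, 4.0, 0.05)

    def run(k: int) -> tm.SeasonSeries:
        if k not in cache:
            stations = tm.grid_release_layout(k, 4.0)
            schedule = tm.make_release_schedule("initial-only", stations, horizon=35)
            state = tm.uniform_infestation_init(grid)
            _, probes = tm.run_spatial_multi_year(
                grid, state, schedule, params_eta065, 35, probes=[(1.0, 1.0)]
            )
            cache[k] = probes[0]
        return cache[k]

    return run


@pytest.fixture
def make_series():
    """Build a SeasonSeries from explicit v/q arrays (diagnostics tests)."""

    def build(v, q=None, years=None) -> tm.SeasonSeries:
        v = np.asarray(v, dtype=float)
        q = np.zeros_like(v) if q is None else np.asarray(q, dtype=float)
        years = np.arange(1, len(v) + 1) if years is None else np.asarray(years)
        return tm.SeasonSeries(
            years=years,
            v_end=v,
            q_end=q,
            p_end=np.zeros_like(v),
            u_end=np.zeros_like(v),
            clamped=np.zeros(len(v), dtype=bool),
        )

    return build
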