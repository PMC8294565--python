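import numpy as np
import pytest

import torymus as tm
from torymus.model_core import NondimensionalParameters


@pytest.fixture
def small_grid() -> tm.SpatialGrid:
    return tm.SpatialGrid(4.0, 4.0, 0.1)


class TestGrid:
    def test_shape_and_centers(self, small_grid):
        assert small_grid.shape == (40, 40)
        assert small_grid.x[0] == pytest.approx(0.05)
        assert small_grid.x[-1] == pytest.approx(3.95)
        assert small_grid.cell_area == pytest.approx(0.01)

    def test_spacing_bound_enforced(self):
        with pytest.raises(tm.InvalidParameterError, match="spacing"):
            tm.SpatialGrid(4.0, 4.0, 0.2)

    def test_nearest_index_and_domain_check(self, small_grid):
        assert small_grid.nearest_index((0.0, 0.0)) == (0, 0)
        iy, ix = small_grid.nearest_index((1.0, 2.0))
        assert abs(small_grid.x[ix] - 1.0) <= small_grid.h / 2 + 1e-12
        assert abs(small_grid.y[iy] - 2.0) <= small_grid.h / 2 + 1e-12
        with pytest.raises(ValueError, match="outside"):
            small_grid.nearest_index((5.0, 1.0))


class TestLaplacian:
    def test_constant_field_maps_to_zero(self, small_grid):
        out = tm.discrete_laplacian(np.full(small_grid.shape, 3.7), small_grid)
        assert np.all(out == 0.0)

    def test_zero_flux_mass_conservation(self, small_grid):
        rng = np.random.default_rng(42)
        fld = rng.random(small_grid.shape)
        out = tm.discrete_laplacian(fld, small_grid)
        assert abs(out.sum() * small_grid.cell_area) < 1e-12

    def test_neumann_eigenfunction_second_order(self):
        """cos(pi x / Lx) is a Neumann eigenfunction; the discrete eigenvalue
        error must shrink ~4x when h is halved."""
        errs = []
        for h in (0.1, 0.05):
            grid = tm.SpatialGrid(4.0, 4.0, h)
            X = np.tile(grid.x, (grid.ny, 1))
            fld = np.cos(np.pi * X / grid.Lx)
            lam = (np.pi / grid.Lx) ** 2
            out = tm.discrete_laplacian(fld, grid)
            errs.append(np.max(np.abs(out + lam * fld)))
        assert errs[1] < errs[0] / 3.0

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError, match="shape"):
            tm.discrete_laplacian(np.zeros((3, 3)), small_grid)


class TestReleases:
    def test_single_cell_release(self, small_grid):
        p = np.zeros(small_grid.shape)
        amount = tm.spatial_engine.apply_releases(p, small_grid, [(0.0, 0.0)])
        assert p[0, 0] == 1.0 and p.sum() == 1.0
        assert amount == pytest.approx(small_grid.cell_area)

    def test_overlapping_releases_clip_at_capacity(self, small_grid):
        p = np.zeros(small_grid.shape)
        tm.spatial_engine.apply_releases(p, small_grid, [(2.0, 2.0), (2.0, 2.0)], amplitude=0.8)
        assert p.max() == 1.0

    def test_disc_footprint_covers_cells(self, small_grid):
        p = np.zeros(small_grid.shape)
        tm.spatial_engine.apply_releases(
            p, small_grid, [(2.0, 2.0)], footprint_radius=0.3
        )
        assert (p == 1.0).sum() > 1

    def test_station_outside_domain_rejected(self, small_grid):
        with pytest.raises(ValueError, match="outside"):
            tm.spatial_engine.apply_releases(
                np.zeros(small_grid.shape), small_grid, [(9.0, 0.0)],
                footprint_radius=0.1,
            )


class TestPhases:
    def test_pure_diffusion_conserves_mass(self, small_grid):
        """With the reaction switched off (tau huge) the parasitoid phase is
        pure diffusion under zero-flux boundaries: total mass is invariant."""
        params = NondimensionalParameters(
            mu=10.0, tau=1e12, E_d=97.5, E_t=33.37, delta=0.5,
            parasitoid_phase_length=1.0, length_unit_km=1.0,
        )
        rng = np.random.default_rng(7)
        p0 = rng.random(small_grid.shape)
        v_prev = np.ones(small_grid.shape)
        p_end, q_end, _ = tm.spatial_engine.spatial_parasitoid_phase(
            p0, v_prev, small_grid, params
        )
        assert p_end.sum() == pytest.approx(p0.sum(), rel=1e-6)
        assert q_end.max() < 1e-9
        # diffusion smooths: the extrema contract
        assert p_end.max() < p0.max() and p_end.min() > p0.min()

    def test_fields_remain_nonnegative(self, small_grid, params_eta065):
        p0 = np.zeros(small_grid.shape)
        p0[0, 0] = 1.0
        v_prev = np.ones(small_grid.shape)
        p_end, q_end, s_end = tm.spatial_engine.spatial_parasitoid_phase(
            p0, v_prev, small_grid, params_eta065
        )
        u_end, v_end = tm.spatial_engine.spatial_wasp_phase(
            s_end, small_grid, params_eta065
        )
        for fld in (p_end, q_end, s_end, u_end, v_end):
            assert np.all(fld >= 0.0)
        assert np.all(q_end <= v_prev + 1e-9)
        assert np.all(v_end <= 1.0)


class TestMultiYearSpatial:
    def test_release_beyond_horizon_rejected(self, small_grid, params_eta065):
        schedule = tm.make_release_schedule(
            "timed", [(0.0, 0.0)], horizon=20, n_r=15
        )
        state = tm.uniform_infestation_init(small_grid)
        with pytest.raises(ValueError, match="horizon"):
            tm.run_spatial_multi_year(
                small_grid, state, schedule, params_eta065, 10
            )

    def test_probe_outside_domain_rejected(self, small_grid, params_eta065):
        state = tm.uniform_infestation_init(small_grid)
        with pytest.raises(ValueError, match="outside"):
            tm.run_spatial_multi_year(
                small_grid, state, None, params_eta065, 2, probes=[(10.0, 1.0)]
            )

    def test_dataset_layout(self, small_grid, params_eta065):
        state = tm.uniform_infestation_init(small_grid)
        schedule = tm.make_release_schedule("initial-only", [(0.0, 0.0)], horizon=2)
        series, _ = tm.run_spatial_multi_year(
            small_grid, state, schedule, params_eta065, 2
        )
        ds = series.to_dataset()
        assert set(ds.data_vars) == {"p", "q", "u", "v"}
        assert ds["v"].dims == ("year", "y", "x")
        assert ds.sizes == {"year": 2, "y": 40, "x": 40}

    def test_uniform_fields_reproduce_homogeneous_engine(self, params_eta065):
        """On spatially uniform fields the Laplacians vanish, so every grid
        cell must follow the homogeneous season map (primary PDE gate)."""
        grid = tm.SpatialGrid(4.0, 4.0, 0.1)
        n_years = 12
        state = tm.SpatialState(
            p=np.full(grid.shape, 1e-9),
            q=np.zeros(grid.shape),
            u=np.zeros(grid.shape),
            v=np.ones(grid.shape),
        )
        spatial, probes = tm.run_spatial_multi_year(
            grid, state, None, params_eta065, n_years,
            probes=[(1.0, 1.0), (3.3, 0.2)],
            rtol=1e-8, atol=1e-14,
        )
        reference = tm.run_multi_year(
            tm.SeasonInput(v_prev=1.0, q_init_adults=1e-9),
            params_eta065, n_years, rtol=1e-8, atol=1e-14,
        )
        for probe in probes:
            np.testing.assert_allclose(probe.v_end, reference.v_end, atol=1e-6)
            np.testing.assert_allclose(probe.q_end, reference.q_end, atol=1e-6)
        # fields stay uniform: no spurious spatial structure appears
        assert np.ptp(spatial.v[-1]) < 1e-9

    def test_grid_convergence_corner_release(self, params_eta065):
        """Halving h from 0.1 to 0.05 moves the probe's log10 pest density by
        less than 0.2 in the corner-release experiment (grid-independent
        release footprint so both grids solve the same continuum problem)."""
        n_years = 9
        logv = {}
        for h in (0.1, 0.05):
            grid = tm.SpatialGrid(4.0, 4.0, h)
            schedule = tm.ReleaseSchedule(
                events=(
                    tm.ReleaseEvent(
                        year=1, stations=((0.0, 0.0),), footprint_radius=0.15
                    ),
                )
            )
            state = tm.uniform_infestation_init(grid)
            _, probes = tm.run_spatial_multi_year(
                grid, state, schedule, params_eta065, n_years, probes=[(1.0, 1.0)]
            )
            logv[h] = np.log10(np.clip(probes[0].v_end, 1e-300, None))
        assert np.max(np.abs(logv[0.1] - logv[0.05])) < 0.2

    def test_recolonization_after_local_suppression(self, corner_release_run):
        """The pest recolonizes the release corner: v drops below 0.1 and later
        returns above 0.9 (the extinction/recolonization cycle)."""
        grid, spatial, _ = corner_release_run
        corner = spatial.v[:, 0, 0]
        suppressed = np.nonzero(corner < 0.1)[0]
        assert suppressed.size > 0
        assert np.max(corner[suppressed[0]:]) > 0.9
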