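"""Stokes–Brinkman solver oracles and transport-metric checks.

The analytic references: plane Poiseuille flow u_max = ΔP·h²/(8μL) and
wall shear ΔP·h/(2L) for an open channel; uniform Darcy velocity
k·ΔP/(μ_gel·L) for a pure porous slab.
"""

import dataclasses

import numpy as np
import pytest

import vasckit as vk
from vasckit.cfd import GEL, LUMEN, DomainGrid


@pytest.fixture(scope="module")
def params():
    return vk.CfdParams()


@pytest.fixture(scope="module")
def poiseuille(params):
    """Open 40-μm channel over the 3-mm device length (anisotropic cells)."""
    lab = np.full((80, 100), LUMEN, dtype=np.int8)
    grid = DomainGrid(lab, (30.0, 0.5))
    return grid, vk.solve_brinkman(grid, params)


@pytest.fixture(scope="module")
def darcy_slab(params):
    lab = np.full((80, 100), GEL, dtype=np.int8)
    grid = DomainGrid(lab, (30.0, 2.5))
    return grid, vk.solve_brinkman(grid, params)


class TestBuildDomains:
    def test_all_gel_mask(self):
        mask = vk.RasterImage(np.zeros((40, 60), bool), 2.0)
        grid = vk.build_domains(mask)
        assert np.all(grid.labels == GEL)

    def test_full_width_strip_is_channel(self):
        m = np.zeros((40, 60), bool)
        m[15:25, :] = True
        grid = vk.build_domains(vk.RasterImage(m, 2.0))
        assert np.all(grid.labels[15:25] == LUMEN)
        assert np.all(grid.labels[:15] == GEL)

    def test_coarsening_preserves_areas(self, network):
        mask, _ = network
        g1 = vk.build_domains(mask)
        g2 = vk.build_domains(mask, coarsen_factor=2)
        a1 = (g1.labels == LUMEN).mean()
        a2 = (g2.labels == LUMEN).mean()
        assert g2.shape[0] == g1.shape[0] // 2
        assert a2 == pytest.approx(a1, rel=0.05)


class TestSolverOracles:
    def test_poiseuille_centerline_velocity(self, poiseuille, params):
        grid, f = poiseuille
        L = grid.length * 1e-6
        h = grid.shape[0] * grid.cell_size[1] * 1e-6
        u_max = params.dP * h**2 / (8 * params.media_viscosity * L)
        assert f.u.max() == pytest.approx(u_max, rel=0.02)

    def test_poiseuille_wall_shear(self, poiseuille, params):
        grid, f = poiseuille
        L = grid.length * 1e-6
        h = grid.shape[0] * grid.cell_size[1] * 1e-6
        tau_wall = params.dP * h / (2 * L)
        assert f.shear.max() == pytest.approx(tau_wall, rel=0.03)

    def test_poiseuille_lumen_mean_velocity(self, poiseuille, params):
        grid, f = poiseuille
        stats = vk.region_stats(f, grid, params)
        u_max = f.u.max() * 1e3
        assert stats.velocity["vessel"][0] == pytest.approx(2 / 3 * u_max,
                                                            rel=0.03)

    def test_darcy_superficial_velocity(self, darcy_slab, params):
        grid, f = darcy_slab
        L = grid.length * 1e-6
        u_darcy = params.k * params.dP / (params.gel_viscosity * L)
        interior = f.u[3:-3, :]
        assert interior.mean() == pytest.approx(u_darcy, rel=0.02)
        # the paper's parameters give 0.233 μm/s
        assert u_darcy * 1e6 == pytest.approx(0.233, rel=0.01)

    def test_darcy_interior_shear_negligible(self, darcy_slab, params):
        grid, f = darcy_slab
        L = grid.length * 1e-6
        u_darcy = params.k * params.dP / (params.gel_viscosity * L)
        h = grid.shape[0] * grid.cell_size[1] * 1e-6
        plug_scale = params.gel_viscosity * u_darcy / h
        assert np.abs(f.shear[10:-10, :]).max() < 0.05 * plug_scale

    def test_zero_pressure_zero_field(self, params):
        lab = np.full((20, 30), GEL, dtype=np.int8)
        grid = DomainGrid(lab, (10.0, 10.0))
        f = vk.solve_brinkman(grid, dataclasses.replace(params, dP=0.0))
        assert np.abs(f.u).max() == 0.0
        assert np.abs(f.v).max() == 0.0

    def test_pressure_drop_linearity(self, params):
        lab = np.full((30, 40), LUMEN, dtype=np.int8)
        lab[10:20, 10:30] = GEL
        grid = DomainGrid(lab, (10.0, 2.0))
        f1 = vk.solve_brinkman(grid, params)
        f3 = vk.solve_brinkman(grid, dataclasses.replace(params, dP=3 * params.dP))
        assert np.allclose(f3.u, 3 * f1.u, rtol=1e-8,
                           atol=1e-12 * np.abs(f1.u).max())
        assert np.allclose(f3.shear, 3 * f1.shear, rtol=1e-8,
                           atol=1e-12 * f1.shear.max())

    def test_mass_conservation_across_sections(self, network, params):
        mask, _ = network
        grid = vk.build_domains(mask, coarsen_factor=4)
        f = vk.solve_brinkman(grid, params)
        q = vk.section_fluxes(f)
        assert np.ptp(q) <= 0.01 * abs(q.mean())

    def test_grid_convergence_straight_channel(self, params):
        means = []
        for ny in (20, 40):
            lab = np.full((ny, 60), LUMEN, dtype=np.int8)
            grid = DomainGrid(lab, (50.0, 40.0 / ny))
            f = vk.solve_brinkman(grid, params)
            means.append(np.abs(f.u).mean())
        assert means[1] == pytest.approx(means[0], rel=0.05)

    def test_divergence_residual_tiny(self, poiseuille):
        _, f = poiseuille
        assert f.divergence_residual < 1e-10


class TestLimitConsistency:
    def test_high_permeability_gel_approaches_poiseuille(self, params):
        """As k → ∞ (drag → 0) a pure-gel channel behaves as an open
        channel with the gel viscosity."""
        lab = np.full((40, 60), GEL, dtype=np.int8)
        grid = DomainGrid(lab, (50.0, 1.0))
        p = dataclasses.replace(params, k=1e-4)
        f = vk.solve_brinkman(grid, p)
        L = grid.length * 1e-6
        h = 40e-6
        u_max = params.dP * h**2 / (8 * params.gel_viscosity * L)
        assert f.u.max() == pytest.approx(u_max, rel=0.02)

    def test_vanishing_lumen_approaches_darcy(self, params):
        lab = np.full((40, 60), GEL, dtype=np.int8)
        lab[20, 30] = LUMEN  # single lumen cell
        grid = DomainGrid(lab, (50.0, 5.0))
        f = vk.solve_brinkman(grid, params)
        L = grid.length * 1e-6
        u_darcy = params.k * params.dP / (params.gel_viscosity * L)
        assert f.u[5:-5].mean() == pytest.approx(u_darcy, rel=0.05)


class TestRegionStats:
    def test_network_gel_velocity_an_order_below_lumen(self, params):
        """Synthetic vessel network: gel-region mean speed at least one
        order of magnitude below the lumen mean."""
        spec = vk.SyntheticNetworkSpec(seed=5, domain_size=(600, 300),
                                       n_nodes=10, width_mean=40.0,
                                       width_sd=4.0, pixel_size=2.0)
        mask, _ = vk.generate_vessel_network(spec)
        grid = vk.build_domains(mask, coarsen_factor=2)
        f = vk.solve_brinkman(grid, params)
        st = vk.region_stats(f, grid, params)
        assert st.velocity["vessel"][0] >= 10 * st.velocity["gel"][0]
        # tissue mean sits between the region means
        assert st.velocity["gel"][0] <= st.velocity["tissue"][0] \
            <= st.velocity["vessel"][0]

    def test_uniform_region_zero_sd(self, darcy_slab, params):
        grid, f = darcy_slab
        st = vk.region_stats(f, grid, params)
        mean, sd = st.velocity["gel"]
        assert sd < 0.15 * mean  # uniform plug up to wall layers

    def test_pore_velocity_reported(self, darcy_slab, params):
        grid, f = darcy_slab
        st = vk.region_stats(f, grid, params)
        assert st.gel_pore_velocity[0] == pytest.approx(
            st.velocity["gel"][0] / params.porosity)

    def test_empty_region_warns(self, poiseuille, params):
        grid, f = poiseuille
        with pytest.warns(UserWarning, match="gel"):
            vk.region_stats(f, grid, params)


class TestTransportMetrics:
    def test_peclet_paper_conditions(self):
        """v·L/D at the measured interstitial velocities, 3-mm channel and
        fibrin diffusivity reproduces Pe ≈ 26 and ≈ 107."""
        assert round(vk.compute_peclet(0.30, 3.0, 34.5)) == 26
        assert round(vk.compute_peclet(1.23, 3.0, 34.5)) == 107

    def test_peclet_zero_velocity(self):
        assert vk.compute_peclet(0.0, 3.0, 34.5) == 0.0

    def test_peclet_invalid_inputs(self):
        with pytest.raises(ValueError):
            vk.compute_peclet(1.0, 0.0, 34.5)
        with pytest.raises(ValueError):
            vk.compute_peclet(1.0, 3.0, -1.0)

    def test_interstitial_shear_scalings(self):
        base = vk.interstitial_shear(1.0, 9.4e-4, 1e-13).tau
        assert vk.interstitial_shear(2.0, 9.4e-4, 1e-13).tau == \
            pytest.approx(2 * base)
        assert vk.interstitial_shear(1.0, 9.4e-4, 0.25e-13).tau == \
            pytest.approx(2 * base)

    def test_interstitial_shear_value_and_label(self):
        est = vk.interstitial_shear(1.23, 9.4e-4, 1e-13)
        assert est.tau == pytest.approx(3.66e-3, rel=0.01)
        assert "sqrt(k)" in est.formula

    def test_invalid_permeability_rejected(self):
        with pytest.raises(ValueError):
            vk.interstitial_shear(1.0, 9.4e-4, 0.0)


class TestParams:
    def test_defaults_are_physical(self, params):
        assert params.media_viscosity == 9.4e-4
        assert params.k == 1e-13

    def test_invalid_porosity(self):
        with pytest.raises(ValueError):
            vk.CfdParams(porosity=1.5)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        path = tmp_path / "p.yaml"
        path.write_text(yaml.safe_dump({"dP": 30.0, "porosity": 0.4}))
        p = vk.CfdParams.from_yaml(path)
        assert p.dP == 30.0
        assert p.porosity == 0.4

    def test_no_inlet_outlet_path_rejected(self):
        lab = np.full((10, 10), GEL, dtype=np.int8)
        lab[:, 5] = 2  # wall across the whole channel
        with pytest.raises(ValueError, match="path"):
            DomainGrid(lab, (1.0, 1.0))
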