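"""Crypt cell-dynamics and solute-diffusion tests (coarse 20-node grid)."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonsim import crypt as C
from colonsim.config import ParameterSet


@pytest.fixture()
def grid(crypt_params):
    return C.CryptGrid(crypt_params.crypt.n_nodes)


@pytest.fixture()
def boundary():
    return C.CryptBoundary(la=0.4, ac=20.0, pro=8.0, but=9.0, h2s=0.15,
                           o2_inner=4.0)


@pytest.fixture(scope="module")
def steady_small_crypt():
    from colonsim.fixtures import small_crypt
    p = small_crypt()
    grid = C.CryptGrid(p.crypt.n_nodes)
    b = C.CryptBoundary(la=0.4, ac=20.0, pro=8.0, but=9.0, h2s=0.15, o2_inner=4.0)
    t0 = time.time()
    out, rep = C.integrate_crypt(C.initial_crypt(grid, p, b), prr=0.5, params=p)
    return p, out, rep, time.time() - t0


class TestDcsProfile:
    def test_confined_to_the_base(self, crypt_params, grid):
        prof = C.dcs_profile(grid, crypt_params)
        assert prof[-1] == 0.0
        assert prof[grid.z > crypt_params.crypt.dcs_cutoff].max() == 0.0
        assert prof[0] == prof.max()

    def test_integral_matches_configured_count(self, crypt_params, grid):
        prof = C.dcs_profile(grid, crypt_params)
        assert np.trapezoid(prof, grid.z) == pytest.approx(
            crypt_params.crypt.dcs_count, rel=1e-12)

    def test_static_across_integration(self, steady_small_crypt):
        p, out, _, _ = steady_small_crypt
        grid = C.CryptGrid(p.crypt.n_nodes)
        assert np.array_equal(out.dcs, C.dcs_profile(grid, p))


class TestPrrActivation:
    def test_boundary_values(self, params):
        assert C.prr_activation(0.0, params) == 0.0
        assert C.prr_activation(params.crypt.prr_half_sat, params) == pytest.approx(0.5)
        assert C.prr_activation(1e9, params) == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.0, 0.2), b=st.floats(0.0, 0.2))
    def test_strictly_increasing(self, params, a, b):
        lo, hi = sorted((a, b))
        if lo < hi:
            assert C.prr_activation(lo, params) < C.prr_activation(hi, params)


class TestBetaOxidation:
    def test_no_butyrate_no_switch(self, params):
        but, o2, sigma = C.beta_oxidation(0.0, 5.0, 0.1, params, rho_diff=100.0)
        assert but == 0.0 and o2 == 0.0 and sigma == 0.0

    def test_h2s_inhibits_the_switch(self, params):
        _, _, s_low = C.beta_oxidation(5.0, 5.0, 0.0, params)
        _, _, s_high = C.beta_oxidation(5.0, 5.0, 50.0, params)
        assert s_high < 0.01 * s_low

    def test_oxygen_to_butyrate_ratio_is_stoichiometric(self, params):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(30):
            but, o2 = rng.uniform(0.1, 20.0), rng.uniform(0.1, 10.0)
            h2s, rho = rng.uniform(0.0, 0.5), rng.uniform(1.0, 2000.0)
            b_use, o_use, _ = C.beta_oxidation(but, o2, h2s, params, rho)
            ratios.append(o_use / b_use)
        assert np.ptp(ratios) < 1e-12
        assert ratios[0] == pytest.approx(params.crypt.beta_ox_o2_per_but)


class TestSoluteProblem:
    def test_no_cells_gives_closed_form_linear_oxygen_profile(self, crypt_params, grid, boundary):
        """Pure diffusion between a base influx and the top Robin exchange:
        c(z) = c_I + j0/k_ex + (j0/D)(1 - z)."""
        cells = np.zeros((4, grid.n))
        sol = C._solve_solutes_quasi_static(cells, boundary, grid, crypt_params)
        cp = crypt_params.crypt
        j0, D, kex = cp.o2_base_flux, cp.o2_diffusion, cp.o2_top_exchange
        expected = boundary.o2_inner + j0 / kex + (j0 / D) * (1.0 - grid.z)
        assert np.allclose(sol[0], expected, rtol=1e-6)

    def test_zero_boundary_butyrate_means_zero_profile(self, crypt_params, grid):
        b = C.CryptBoundary(la=0.0, ac=0.0, pro=0.0, but=0.0, h2s=0.0, o2_inner=1.0)
        cells = np.zeros((4, grid.n))
        cells[3] = 500.0
        sol = C._solve_solutes_quasi_static(cells, b, grid, crypt_params)
        assert np.abs(sol[C._ISOL["but"]]).max() < 1e-12

    def test_quasi_static_solution_is_stationary_for_the_dynamic_rhs(
            self, crypt_params, grid, boundary, steady_small_crypt):
        _, out, _, _ = steady_small_crypt
        rhs = C.crypt_solute_rhs(out.solutes, out.cells, boundary, grid, crypt_params)
        assert np.abs(rhs).max() / (np.abs(out.solutes).max() + 1e-12) < 1e-6


class TestCellDynamics:
    def test_sink_only_dynamics_never_gains_cells(self, crypt_params, grid, boundary):
        doc = crypt_params.model_dump(mode="python")
        doc["crypt"]["sc_division"] = 0.0
        doc["crypt"]["pc_division"] = 0.0
        doc["crypt"]["sc_to_pc"] = 0.0
        doc["crypt"]["pc_differentiation"] = 0.0
        p2 = ParameterSet.model_validate(doc)
        state = C.initial_crypt(grid, p2, boundary)
        d = C.crypt_cell_rhs(state.cells, state.solutes, state.dcs, 0.5, grid, p2)
        assert (d.sum(axis=0) * grid.dz).sum() <= 1e-12

    def test_prr_stimulation_raises_proliferative_count(self, crypt_params, boundary):
        grid = C.CryptGrid(crypt_params.crypt.n_nodes)
        counts = {}
        for prr in (0.0, 1.0):
            out, _ = C.integrate_crypt(C.initial_crypt(grid, crypt_params, boundary),
                                       prr=prr, params=crypt_params)
            counts[prr] = C.crypt_summary(out, crypt_params).proliferative_cells
        assert counts[1.0] > counts[0.0]

    def test_goblet_enterocyte_ratio_is_one_third(self, steady_small_crypt):
        p, out, _, _ = steady_small_crypt
        info = C.crypt_summary(out, p)
        assert info.goblet_to_enterocyte == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_spatial_zonation(self, steady_small_crypt):
        """Stem niche below the proliferative zone below the differentiated zone."""
        p, out, _, _ = steady_small_crypt
        z = out.grid.z

        def centroid(rho):
            return np.trapezoid(rho * z, z) / np.trapezoid(rho, z)

        c_sc = centroid(out.cells[0])
        c_pc = centroid(out.cells[1])
        c_diff = centroid(out.cells[2] + out.cells[3])
        assert c_sc < c_pc < c_diff

    def test_transport_loses_cells_only_through_mouth_shedding(
            self, crypt_params, grid, boundary):
        """With all sources off, the discrete cell budget closes exactly:
        d/dt of the total cell content equals minus the shedding sink (the
        crowding transport itself moves cells without creating or destroying
        them)."""
        doc = crypt_params.model_dump(mode="python")
        for knob in ("sc_division", "pc_division", "sc_to_pc",
                     "pc_differentiation", "diff_cell_loss", "cell_diffusion"):
            doc["crypt"][knob] = 0.0
        p2 = ParameterSet.model_validate(doc)
        state = C.initial_crypt(grid, p2, boundary)
        d = C.crypt_cell_rhs(state.cells, state.solutes, state.dcs, 0.5, grid, p2)
        cp = p2.crypt
        shed = cp.shedding_rate * np.exp(-(((1.0 - grid.z) / cp.shedding_width) ** 2))
        total_rate = d.sum() * grid.dz              # finite-volume content
        shed_total = (shed * state.cells.sum(axis=0)).sum() * grid.dz
        assert total_rate == pytest.approx(-shed_total, rel=1e-12)

    def test_converges_quickly_on_the_coarse_grid(self, steady_small_crypt):
        _, _, rep, elapsed = steady_small_crypt
        assert rep["converged"]
        assert elapsed < 30.0


class TestSteadyStateProperties:
    def test_quasi_static_and_dynamic_modes_agree(self, crypt_params, boundary):
        doc = crypt_params.model_dump(mode="python")
        doc["solver"]["crypt_stationarity_tol"] = 1e-7   # resolve both modes fully
        doc["solver"]["crypt_t_max"] = 4000.0
        p2 = ParameterSet.model_validate(doc)
        grid = C.CryptGrid(p2.crypt.n_nodes)
        start = C.initial_crypt(grid, p2, boundary)
        qs, _ = C.integrate_crypt(start, prr=0.5, params=p2, quasi_static=True)
        dyn, _ = C.integrate_crypt(start, prr=0.5, params=p2, quasi_static=False)
        a = C.crypt_summary(qs, p2)
        b = C.crypt_summary(dyn, p2)
        assert a.total_cells == pytest.approx(b.total_cells, rel=1e-4)
        assert a.differentiated_cells == pytest.approx(b.differentiated_cells, rel=1e-4)

    def test_grid_refinement_stability(self, crypt_params, boundary):
        """Doubling the grid in the asymptotic range moves counts < 0.5%."""
        counts = {}
        for n in (50, 100):
            doc = crypt_params.model_dump(mode="python")
            doc["crypt"]["n_nodes"] = n
            p2 = ParameterSet.model_validate(doc)
            grid = C.CryptGrid(n)
            out, _ = C.integrate_crypt(C.initial_crypt(grid, p2, boundary),
                                       prr=0.5, params=p2)
            counts[n] = C.crypt_summary(out, p2).total_cells
        assert abs(counts[100] - counts[50]) / counts[50] < 0.005

    def test_differentiated_count_monotone_in_butyrate(self, crypt_params):
        grid = C.CryptGrid(crypt_params.crypt.n_nodes)
        outs = []
        for but in (1.0, 6.0, 15.0):
            b = C.CryptBoundary(la=0.4, ac=20.0, pro=8.0, but=but, h2s=0.1,
                                o2_inner=4.0)
            out, _ = C.integrate_crypt(C.initial_crypt(grid, crypt_params, b),
                                       prr=0.5, params=crypt_params)
            outs.append(C.crypt_summary(out, crypt_params).differentiated_cells)
        assert outs[0] <= outs[1] <= outs[2]
        assert outs[2] > outs[0]

    def test_h2s_weakens_oxygen_consumption(self, crypt_params):
        """More boundary H2S: less beta-oxidation, more O2 left at the top."""
        grid = C.CryptGrid(crypt_params.crypt.n_nodes)
        tops = []
        for h2s in (0.0, 5.0):
            b = C.CryptBoundary(la=0.4, ac=20.0, pro=8.0, but=9.0, h2s=h2s,
                                o2_inner=4.0)
            out, _ = C.integrate_crypt(C.initial_crypt(grid, crypt_params, b),
                                       prr=0.5, params=crypt_params)
            tops.append(out.solutes[C._ISOL["O2"]][-1])
        assert tops[1] >= tops[0]

    def test_solute_budget_closes_at_steady_state(self, steady_small_crypt):
        """Boundary influx balances absorption + beta-oxidation for butyrate.

        Summing the discrete steady equations telescopes the Laplacian, so
        D/dz^2 * [(c1 - c0) + (c_top_boundary - c_top)] must equal the total
        sink evaluated node-wise with the true Monod forms.
        """
        p, out, _, _ = steady_small_crypt
        grid, cp = out.grid, p.crypt
        c = out.solutes[C._ISOL["but"]]
        a = cp.metabolite_diffusion / grid.dz**2
        influx = a * ((c[1] - c[0]) + (out.boundary.but - c[-1]))
        ent = out.cells[3]
        sat = np.where(c > 0, c / (cp.metabolite_half_sat + c), 0.0)
        absorption = (cp.metabolite_absorption * ent * sat).sum()
        b_use, _, _ = C.beta_oxidation(c, out.solutes[C._ISOL["O2"]],
                                       out.boundary.h2s, p, out.cells[2] + ent)
        assert influx == pytest.approx(absorption + b_use.sum(), rel=1e-6)


class TestCryptSummary:
    def test_counts_are_trapezoidal_integrals(self, steady_small_crypt):
        p, out, _, _ = steady_small_crypt
        info = C.crypt_summary(out, p)
        for k, name in enumerate(C.CELL_TYPES):
            assert info.counts[name] == pytest.approx(
                np.trapezoid(out.cells[k], out.grid.z))

    def test_empty_crypt_gives_zero_counts(self, crypt_params, grid, boundary):
        state = C.initial_crypt(grid, crypt_params, boundary)
        state.cells[:] = 0.0
        info = C.crypt_summary(state, crypt_params)
        assert info.total_cells == 0.0
        assert info.goblet_to_enterocyte == 0.0
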