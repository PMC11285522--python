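"""Flow operators, balancing solver and section ODE tests."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from colonsim.config import reference_diet
from colonsim.fixtures import diffusion_only, random_state
from colonsim.metabolism import ProcessNetwork
from colonsim import section as S
from colonsim.registry import BACT_SLICE, ID, IV, IX, N_D, N_V, SOLID_MASK


def uniform_input_state(inp):
    """State whose three compartments all equal the input composition."""
    f = np.tile(inp.f_in, (3, 1)) * SOLID_MASK
    f[:, IV["l"]] += 1.0 - f.sum(axis=1)      # re-close excluded components
    c = np.tile(inp.c_in, (3, 1))
    return S.SectionState(f, c, 0.0)


@pytest.fixture()
def diff_setup():
    params = diffusion_only()
    net = ProcessNetwork(params)
    inp = S.SectionInput.from_diet(reference_diet(), params)
    return params, net, inp


class TestTransitFlow:
    def test_balanced_throughflow_cancels(self, diff_setup):
        params, net, inp = diff_setup
        st = uniform_input_state(inp)
        st.f[0] = inp.f_in                     # lumen exactly the input mix
        dfi, dci = S.transit_flow(st, inp, params)
        q = inp.v_in * params.geometry.area_in
        dfo, dco = S._transit_outflow(st, q, params)
        # bacteria are retained, so only the non-bacterial part cancels exactly
        no_b = ~np.zeros(N_V, bool)
        no_b[BACT_SLICE] = False
        resid = (dfi + dfo)[0][no_b[None, :].repeat(1, 0).ravel()[:no_b.sum()]] \
            if False else (dfi + dfo)[0][8:]
        assert np.abs(dco + dci).max() < 1e-12
        # retained bacteria: inflow exceeds outflow
        assert ((dfi + dfo)[0][BACT_SLICE] >= 0).all()

    def test_washout_is_exponential_with_rate_v_over_length(self, diff_setup):
        params, net, _ = diff_setup
        inp = S.SectionInput(np.zeros(N_V), np.zeros(N_D), v_in=0.416)
        st = random_state(7)
        q = inp.v_in * params.geometry.area_out
        dfo, dco = S._transit_outflow(st, q, params)
        rate = inp.v_in * params.geometry.area_out / params.geometry.volume_L
        assert np.allclose(dco[0], -rate * st.c[0], rtol=1e-12)
        # the volumetric outflow totals q even with bacterial retention
        assert dfo[0].sum() * params.geometry.volume_L == pytest.approx(-q)

    def test_no_transit_contribution_in_mucus_compartments(self, diff_setup):
        params, _, inp = diff_setup
        st = random_state(3)
        dfi, dci = S.transit_flow(st, inp, params)
        dfo, dco = S._transit_outflow(st, 1.0, params)
        for arr in (dfi, dci, dfo, dco):
            assert not arr[1:].any()


class TestSecretionFlow:
    def test_zero_cells_zero_secretion(self, params):
        epi = S.EpithelialSummary(0.0, 0.0, 0.0, 0.3, 0.0)
        df, dc = S.secretion_flow(random_state(1), epi, params)
        assert not df.any() and not dc.any()

    def test_no_prr_stimulation_gives_exactly_basal(self, params):
        epi0 = S.EpithelialSummary(400.0, 1200.0, 1e5, 0.0, 0.0)
        assert S.mucus_production_rate(epi0, params) == pytest.approx(
            400.0 * 1e5 * params.secretion.mucus_per_goblet)

    def test_mucus_flux_bookkeeping_across_gamma_O(self, params, network):
        """Mucus is conserved at the interfaces: the combined I+O mucus budget
        equals sources (secretion + metabolism) minus the export into the
        lumen, i.e. nothing is lost crossing Gamma_O."""
        inp = S.SectionInput.from_diet(reference_diet(), params)
        st = S.initial_state(inp, params)
        epi = S.EpithelialSummary.reference(params)
        g = params.geometry
        df, dc, flow = S._assemble(st, inp, epi, params, network)
        m = IV["m"]
        F_I, _ = network.metabolic_rhs(st.f[2], st.c[2], "I")
        F_O, _ = network.metabolic_rhs(st.f[1], st.c[1], "O")
        q_mucus = S.mucus_production_rate(epi, params)
        # mucus exported O -> L rides the outward interface flux
        flux_OL = flow.v_m_OL * g.area_gamma_L * st.f[1].sum()
        exported = max(flux_OL, 0.0) * st.f[1, m] / st.f[1].sum()
        total_change = df[2, m] * g.volume_I + df[1, m] * g.volume_O
        sources = q_mucus + F_I[m] * g.volume_I + F_O[m] * g.volume_O
        assert total_change == pytest.approx(sources - exported, rel=1e-9)


class TestAbsorptionFlow:
    def test_zero_enterocytes_zero_absorption(self, params):
        epi = S.EpithelialSummary(400.0, 0.0, 1e5, 0.3, 0.0)
        df, dc = S.absorption_flow(random_state(2), epi, params)
        assert not df.any() and not dc.any()

    def test_sink_ordering_toward_the_wall(self, params):
        """At equal concentrations the uptake term is largest in I."""
        st = random_state(4)
        st.c[:] = 10.0
        st.f[:, IV["l"]] = 0.5
        epi = S.EpithelialSummary(400.0, params.absorption.n_ent_ref, 1e5, 0.3, 0.0)
        a = params.absorption
        sinks = (a.metabolite_rate_L, a.metabolite_rate_O, a.metabolite_rate_I)
        assert sinks[2] > sinks[1] > sinks[0]
        df, dc = S.absorption_flow(st, epi, params)
        j = ID["but"]
        assert dc[IX["L"], j] == pytest.approx(-a.metabolite_rate_L * 10.0)
        assert dc[IX["O"], j] == pytest.approx(-a.metabolite_rate_O * 10.0)

    def test_liquid_absorption_triggers_rebalancing(self, params, network):
        """A lumen liquid sink must be compensated by a reduced outflow."""
        inp = S.SectionInput.from_diet(reference_diet(), params)
        st = uniform_input_state(inp)
        epi = S.EpithelialSummary.reference(params)
        flow = S.solve_balancing_flows(st, inp, epi, params, network)
        assert flow.v_out < flow.v_in


class TestDiffusionFlow:
    def test_no_gradient_no_flux(self, params):
        st = random_state(5)
        st.c[:] = st.c[0]
        df, dc = S.diffusion_flow(st, params)
        assert np.abs(dc).max() < 1e-12

    def test_diffusion_conserves_dissolved_amounts(self, diff_setup):
        """Integrating pure exchange keeps sum_x c_j^x V_x constant."""
        params, _, _ = diff_setup
        vols = np.array(params.geometry.volumes())
        st = random_state(6)

        def rhs(t, y):
            sti = S.SectionState(st.f, y.reshape(3, N_D), t)
            _, dc = S.diffusion_flow(sti, params)
            return dc.ravel()

        sol = solve_ivp(rhs, (0, 50), st.c.ravel(), rtol=1e-10, atol=1e-12)
        c0 = st.c
        c1 = sol.y[:, -1].reshape(3, N_D)
        assert np.allclose(vols @ c1, vols @ c0, rtol=1e-8)
        # equilibration: diffusing species end close to the volume-weighted mean
        j = ID["H2"]
        assert np.ptp(c1[:, j]) < 0.05 * max(np.ptp(c0[:, j]), 1e-12)


class TestMotilityFlow:
    def test_nothing_to_move(self, params):
        st = random_state(8)
        st.f[IX["L"], BACT_SLICE] = 0.0
        df, dc = S.motility_flow(st, params)
        assert not df.any()

    def test_no_flux_into_inner_mucus_ever(self, params):
        for seed in range(10):
            df, _ = S.motility_flow(random_state(seed), params)
            assert not df[IX["I"]].any()
            # pure L -> O transfer conserves bacterial amount
            vols = params.geometry.volumes()
            moved = df[IX["L"], BACT_SLICE] * vols[0] + df[IX["O"], BACT_SLICE] * vols[1]
            assert np.abs(moved).max() < 1e-15


class TestBalancingFlows:
    def test_nothing_to_compensate(self, diff_setup):
        """No secretion/absorption/motility/metabolism: v_out = v_in, no mucus flow."""
        params, net, inp = diff_setup
        doc = params.model_dump(mode="python")
        tiny = 1e-12
        doc["absorption"]["metabolite_rate_L"] = 0.0
        doc["absorption"]["metabolite_rate_O"] = tiny
        doc["absorption"]["metabolite_rate_I"] = 2 * tiny
        doc["absorption"]["liquid_rate_L"] = 0.0
        doc["absorption"]["liquid_rate_O"] = tiny
        doc["absorption"]["liquid_rate_I"] = 2 * tiny
        from colonsim.config import ParameterSet
        p2 = ParameterSet.model_validate(doc)
        net2 = ProcessNetwork(p2)
        st = uniform_input_state(inp)
        st.f[0] = inp.f_in
        epi = S.EpithelialSummary(0.0, 0.0, 0.0, 0.0, 0.0)
        flow = S.solve_balancing_flows(st, inp, epi, p2, net2)
        assert flow.v_out == pytest.approx(flow.v_in, rel=1e-9)
        assert abs(flow.v_m_IO) < 1e-9 and abs(flow.v_m_OL) < 1e-9

    def test_hand_solved_liquid_absorption_fixture(self, diff_setup):
        """Pure liquid absorption: the three budgets solved by hand."""
        params, _, inp = diff_setup
        doc = params.model_dump(mode="python")
        lL, lO, lI = 0.01, 0.02, 0.03
        doc["absorption"]["liquid_rate_L"] = lL
        doc["absorption"]["liquid_rate_O"] = lO
        doc["absorption"]["liquid_rate_I"] = lI
        from colonsim.config import ParameterSet
        p2 = ParameterSet.model_validate(doc)
        net2 = ProcessNetwork(p2)
        st = uniform_input_state(inp)
        st.f[0] = inp.f_in
        epi = S.EpithelialSummary(0.0, p2.absorption.n_ent_ref,
                                  p2.geometry.crypts_per_section, 0.0, 0.0)
        g = p2.geometry
        vL, vO, vI = g.volumes()
        flow = S.solve_balancing_flows(st, inp, epi, p2, net2)
        # innermost budget: liquid sink in I drawn from O (inward => negative)
        flux_IO = -lI * st.f[2, IV["l"]] * vI
        v_IO = flux_IO / (g.area_gamma_O * st.f[1, IV["l"]])
        assert flow.v_m_IO == pytest.approx(v_IO, rel=1e-9)
        # O budget: its own sink plus the liquid pulled into I, drawn from L
        flux_OL = (-lO * st.f[1, IV["l"]] * vO) + flux_IO
        v_OL = flux_OL / (g.area_gamma_L * st.f[0, IV["l"]])
        assert flow.v_m_OL == pytest.approx(v_OL, rel=1e-9)
        # lumen: inflow minus all water losses
        q_out = inp.v_in * g.area_in - lL * st.f[0, IV["l"]] * vL + flux_OL
        assert flow.v_out == pytest.approx(q_out / g.area_out, rel=1e-9)
        assert 0 < flow.v_out < flow.v_in

    def test_volume_budgets_closed_at_random_states(self, params, network):
        inp = S.SectionInput.from_diet(reference_diet(), params)
        epi = S.EpithelialSummary.reference(params)
        for seed in range(25):
            st = random_state(seed)
            df, dc, _ = S._assemble(st, inp, epi, params, network)
            assert np.abs(df.sum(axis=1)).max() < 1e-10


class TestSectionIntegration:
    def test_fixed_point_returns_immediately(self, diff_setup):
        """A uniform no-reaction state with matched input is stationary."""
        params, net, inp = diff_setup
        doc = params.model_dump(mode="python")
        tiny = 1e-12
        doc["absorption"]["metabolite_rate_L"] = 0.0
        doc["absorption"]["metabolite_rate_O"] = tiny
        doc["absorption"]["metabolite_rate_I"] = 2 * tiny
        doc["absorption"]["liquid_rate_L"] = 0.0
        doc["absorption"]["liquid_rate_O"] = tiny
        doc["absorption"]["liquid_rate_I"] = 2 * tiny
        from colonsim.config import ParameterSet
        p2 = ParameterSet.model_validate(doc)
        net2 = ProcessNetwork(p2)
        # inert input: no bacteria (retention would otherwise accumulate them)
        f_in = inp.f_in.copy()
        f_in[BACT_SLICE] = 0.0
        f_in[IV["l"]] = 1.0 - f_in.sum() + f_in[IV["l"]]
        inp2 = S.SectionInput(f_in, np.zeros(N_D), inp.v_in)
        st = uniform_input_state(inp2)
        st.f[:] = inp2.f_in * SOLID_MASK
        st.f[:, IV["l"]] += 1.0 - st.f.sum(axis=1)
        st.c[:] = 0.0
        epi = S.EpithelialSummary(0.0, 0.0, 0.0, 0.0, 0.0)
        out, rep = S.integrate_to_steady_state(st, inp2, epi, p2, net=net2)
        assert rep.converged and rep.t_final == 0.0
        assert np.array_equal(out.f, st.f)

    def test_default_horizon_is_400_hours(self, params):
        assert params.solver.t_max == 400.0

    def test_trajectory_invariants(self, params, network):
        """Sum-to-one, non-negativity and forbidden zones along a trajectory."""
        inp = S.SectionInput.from_diet(reference_diet(), params)
        st0 = S.initial_state(inp, params)
        epi = S.EpithelialSummary.reference(params)

        def rhs(t, y):
            sti = S.unpack(y, t)
            df, dc, _ = S._assemble(sti, inp, epi, params, network)
            return np.concatenate([df[SOLID_MASK], dc.ravel()])

        sol = solve_ivp(rhs, (0, 80), S.pack(st0), method="LSODA",
                        rtol=params.solver.rtol, atol=1e-10,
                        t_eval=np.linspace(0, 80, 60))
        assert sol.success
        for k in range(sol.y.shape[1]):
            sti = S.unpack(sol.y[:, k])
            assert np.abs(sti.f.sum(axis=1) - 1.0).max() < 1e-6
            assert sti.f.min() > -1e-8 and sti.c.min() > -1e-8
            assert not sti.f[~SOLID_MASK].any()
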