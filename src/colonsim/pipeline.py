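"""Bidirectional crypt-section coupling and the five-section pipeline.

Each colon section is solved as a joint fixed point of two sub-models: the
compartmental flow/metabolism ODEs (given epithelial secretion/absorption
capacities) and the crypt PDEs (given the inner-mucus concentrations and the
outer-mucus bacterial fraction that sets PRR activation).  The two are
alternated with a damped update of the epithelial summary until every
coupling quantity is stationary.

The full simulation chains five sections: each downstream section receives
the upstream steady lumen composition as its input and the upstream steady
outflow as its inflow (volume constancy across sections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DietInput, ParameterSet
from .crypt import (CryptBoundary, CryptGrid, CryptState, CryptSummary,
                    crypt_summary, initial_crypt, integrate_crypt,
                    prr_activation)
from .metabolism import ProcessNetwork
from .registry import ID, IX
from .section import (ConvergenceReport, EpithelialSummary, FlowField,
                      SectionInput, SectionState, initial_state,
                      integrate_to_steady_state, solve_balancing_flows)


@dataclass
class SectionResult:
    """Converged coupled state of one colon section."""

    index: int
    input: SectionInput
    state: SectionState
    crypt: CryptState
    crypt_info: CryptSummary
    flow: FlowField
    epithelium: EpithelialSummary
    report: ConvergenceReport
    coupling_iterations: int
    coupling_residual: float


@dataclass
class PipelineRun:
    sections: list[SectionResult]
    diet: DietInput
    scenario: object | None
    params: ParameterSet

    @property
    def final(self) -> SectionResult:
        return self.sections[-1]


class CouplingError(RuntimeError):
    """Outer crypt-section iteration failed to converge."""

    def __init__(self, msg: str, last: SectionResult | None = None):
        super().__init__(msg)
        self.last = last


def couple(crypt_state: CryptState, f_b_outer: float,
           params: ParameterSet) -> EpithelialSummary:
    """Epithelial summary the section model needs, from a relaxed crypt.

    Secretion and absorption capacities scale with per-crypt cell counts
    times the number of crypts in the section; the crypt-top O2 flux becomes
    the inner-mucus oxygen source; PRR activation is re-evaluated from the
    current outer-mucus bacterial fraction.
    """
    info = crypt_summary(crypt_state, params)
    return EpithelialSummary(
        goblet_cells=info.counts["gc"],
        enterocytes=info.counts["ent"],
        crypts=params.geometry.crypts_per_section,
        prr_activation=prr_activation(f_b_outer, params),
        o2_flux_per_crypt=info.o2_top_flux_per_crypt,
    )


def boundary_from_state(state: SectionState, params: ParameterSet,
                        o2_base_flux: float | None = None) -> CryptBoundary:
    """Crypt boundary forcing from the inner-mucus concentrations."""
    cI = state.c[IX["I"]]
    def nn(j: str) -> float:
        return float(max(cI[ID[j]], 0.0))
    return CryptBoundary(la=nn("la"), ac=nn("ac"), pro=nn("pro"), but=nn("but"),
                         h2s=nn("H2S"), o2_inner=nn("O2"),
                         o2_base_flux=o2_base_flux)


def _epi_residual(old: EpithelialSummary, new: EpithelialSummary) -> float:
    pairs = [(old.goblet_cells, new.goblet_cells),
             (old.enterocytes, new.enterocytes),
             (old.prr_activation, new.prr_activation),
             (old.o2_flux_per_crypt, new.o2_flux_per_crypt)]
    return max(abs(a - b) / (abs(a) + abs(b) + 1e-12) for a, b in pairs)


def _damp(old: EpithelialSummary, new: EpithelialSummary, w: float) -> EpithelialSummary:
    mix = lambda a, b: (1.0 - w) * a + w * b
    return EpithelialSummary(
        goblet_cells=mix(old.goblet_cells, new.goblet_cells),
        enterocytes=mix(old.enterocytes, new.enterocytes),
        crypts=new.crypts,
        prr_activation=mix(old.prr_activation, new.prr_activation),
        o2_flux_per_crypt=mix(old.o2_flux_per_crypt, new.o2_flux_per_crypt),
    )


@dataclass
class _WarmStart:
    state: SectionState | None = None
    crypt: CryptState | None = None
    epi: EpithelialSummary | None = None


def run_section(inp: SectionInput, params: ParameterSet, index: int = 1,
                o2_base_flux: float | None = None,
                warm: _WarmStart | None = None,
                net: ProcessNetwork | None = None) -> SectionResult:
    """Solve one section to its coupled crypt-flows fixed point.

    ``o2_base_flux`` overrides the crypt's basal oxygen supply (breach
    scenarios); ``warm`` seeds the iteration with a nearby solution.
    """
    sp = params.solver
    net = net or ProcessNetwork(params)
    warm = warm or _WarmStart()
    grid = CryptGrid(params.crypt.n_nodes)

    sec_state = warm.state.copy() if warm.state is not None else initial_state(inp, params)
    epi = warm.epi or EpithelialSummary.reference(params)
    crypt_state = warm.crypt

    residual = np.inf
    it = 0
    report: ConvergenceReport | None = None
    for it in range(1, sp.coupling_max_iter + 1):
        sec_state, report = integrate_to_steady_state(sec_state, inp, epi, params, net=net)
        boundary = boundary_from_state(sec_state, params, o2_base_flux)
        if crypt_state is None:
            crypt_state = initial_crypt(grid, params, boundary)
        else:
            crypt_state = CryptState(grid, crypt_state.cells.copy(), crypt_state.dcs,
                                     crypt_state.solutes.copy(), boundary)
        f_b_outer = float(sec_state.f_B[IX["O"]])
        crypt_state, _ = integrate_crypt(crypt_state, prr_activation(f_b_outer, params),
                                         params)
        epi_new = couple(crypt_state, f_b_outer, params)
        residual = _epi_residual(epi, epi_new)
        epi = _damp(epi, epi_new, sp.coupling_relaxation)
        if residual < sp.coupling_tol:
            break
    info = crypt_summary(crypt_state, params)
    flow = solve_balancing_flows(sec_state, inp, epi, params, net)
    result = SectionResult(index, inp, sec_state, crypt_state, info, flow, epi,
                           report, it, residual)
    if residual >= sp.coupling_tol:
        raise CouplingError(
            f"section {index}: coupling residual {residual:.2e} after {it} "
            f"iterations (tol {sp.coupling_tol:g})", last=result)
    return result


def run_pipeline(diet: DietInput, params: ParameterSet,
                 scenario=None, n_sections: int = 5) -> PipelineRun:
    """Sequential simulation of ``n_sections`` colon sections.

    Section k+1 receives section k's steady lumen composition and outflow.
    A scenario (epithelial breach) perturbs only its designated sections'
    parameters; downstream sections inherit the perturbed upstream state but
    run with unperturbed local parameters.
    """
    from .experiments import apply_scenario  # local import to avoid a cycle

    results: list[SectionResult] = []
    inp = SectionInput.from_diet(diet, params)
    warm = _WarmStart()
    for k in range(1, n_sections + 1):
        local_params = apply_scenario(scenario, k, params) if scenario is not None else params
        net = ProcessNetwork(local_params)
        try:
            res = run_section(inp, local_params, index=k, warm=warm, net=net)
        except CouplingError as exc:
            raise CouplingError(
                f"pipeline aborted at section {k}: {exc}", last=exc.last) from exc
        results.append(res)
        inp = SectionInput.from_handoff(res.state, v_in=res.flow.v_out)
        warm = _WarmStart(state=res.state, crypt=res.crypt, epi=res.epithelium)
    return PipelineRun(results, diet, scenario, params)
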