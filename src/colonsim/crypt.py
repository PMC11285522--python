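"""Space-structured colonic crypt: cell populations and solute diffusion.

The crypt axis is normalised to z in [0, 1] (0 = base, 1 = top).  Four mobile
cell types — stem cells (sc), progenitors (pc), goblet cells (gc) and
enterocytes (ent) — evolve as densities (cells per unit z) under
crowding-driven transport (cells push each other toward the top), division,
differentiation and top extrusion; deep crypt secretory cells (dcs) are a
static base-concentrated profile.  Five solutes diffuse along the axis:
oxygen enters as a flux at the base (vessels beneath the epithelium) and
leaves into the inner mucus at the top; lactate, acetate, propionate and
butyrate enter at the top with the inner-mucus concentrations as Dirichlet
conditions and are consumed on the way down.

Differentiated cells run an oxygen-consuming beta-oxidation of butyrate,
modulated by a metabolic switch sigma(z) that butyrate activates and H2S
inhibits; this is what keeps the crypt top (and hence the lumen) hypoxic
when fibre intake sustains butyrate production.

Division of stem and progenitor cells is stimulated by pattern-recognition
receptor (PRR) activation, a saturating function of the bacterial volume
fraction in the outer mucus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .config import CryptParams, ParameterSet

CELL_TYPES = ("sc", "pc", "gc", "ent")
CRYPT_SOLUTES = ("O2", "la", "ac", "pro", "but")
_ISOL = {s: i for i, s in enumerate(CRYPT_SOLUTES)}


@dataclass(frozen=True)
class CryptGrid:
    """Uniform grid on the normalised crypt axis."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("crypt grid needs at least 8 nodes")

    @property
    def z(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n)

    @property
    def dz(self) -> float:
        return 1.0 / (self.n - 1)


@dataclass(frozen=True)
class CryptBoundary:
    """Inner-mucus concentrations the crypt is exposed to at its top, plus
    the basal oxygen supply (possibly perturbed by a breach scenario)."""

    la: float = 0.0
    ac: float = 0.0
    pro: float = 0.0
    but: float = 0.0
    h2s: float = 0.0
    o2_inner: float = 0.0          # c_O2 in the inner mucus (Robin condition)
    o2_base_flux: float | None = None   # overrides params.crypt.o2_base_flux

    def __post_init__(self) -> None:
        vals = [self.la, self.ac, self.pro, self.but, self.h2s, self.o2_inner]
        if any(v < 0 for v in vals):
            raise ValueError("boundary concentrations must be non-negative")


@dataclass
class CryptState:
    grid: CryptGrid
    cells: np.ndarray              # (4, n): sc, pc, gc, ent
    dcs: np.ndarray                # (n,), static
    solutes: np.ndarray            # (5, n): O2, la, ac, pro, but
    boundary: CryptBoundary

    def copy(self) -> "CryptState":
        return CryptState(self.grid, self.cells.copy(), self.dcs,
                          self.solutes.copy(), self.boundary)


@dataclass
class CryptSummary:
    """Aggregates the section model consumes, plus diagnostics."""

    counts: dict[str, float]
    total_cells: float
    proliferative_cells: float
    differentiated_cells: float
    goblet_to_enterocyte: float
    o2_base_to_top: float
    o2_top_flux_per_crypt: float
    base_concentrations: dict[str, float]


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def dcs_profile(grid: CryptGrid, params: ParameterSet) -> np.ndarray:
    """Static deep-crypt-secretory-cell density: a base bump, zero above the
    cutoff height, normalised so its integral equals the configured count."""
    cp = params.crypt
    z = grid.z
    prof = np.exp(-((z / cp.dcs_width) ** 2))
    prof[z > cp.dcs_cutoff] = 0.0
    total = np.trapezoid(prof, z)
    if total > 0:
        prof *= cp.dcs_count / total
    return prof


def prr_activation(f_b_outer: float, params: ParameterSet) -> float:
    """PRR activation R(f_B^O) in [0, 1]: Hill saturation of the bacterial
    volume fraction in the outer mucus."""
    if f_b_outer < 0:
        raise ValueError("bacterial fraction must be non-negative")
    cp = params.crypt
    x = f_b_outer**cp.prr_hill
    return float(x / (cp.prr_half_sat**cp.prr_hill + x))


def beta_oxidation(c_but, c_o2, c_h2s, params: ParameterSet,
                   rho_diff: float | np.ndarray = 1.0):
    """Beta-oxidation terms: (butyrate use, O2 use, switch level sigma).

    sigma = activation(butyrate) * inhibition(H2S); consumption is
    sigma * rho_diff * r * M(but) * M(O2), with oxygen consumed at a fixed
    stoichiometric ratio to butyrate.
    """
    cp = params.crypt
    c_but = np.asarray(c_but, float)
    c_o2 = np.asarray(c_o2, float)
    act = c_but / (cp.but_switch_half_sat + c_but + 1e-300)
    act = np.where(c_but > 0, act, 0.0)
    inh = 1.0 / (1.0 + (np.maximum(c_h2s, 0.0) / cp.h2s_switch_threshold) ** cp.h2s_switch_hill)
    sigma = act * inh
    m_but = np.where(c_but > 0, c_but / (cp.but_switch_half_sat + c_but + 1e-300), 0.0)
    m_o2 = np.where(c_o2 > 0, c_o2 / (cp.o2_half_sat + c_o2 + 1e-300), 0.0)
    but_use = cp.beta_ox_rate * sigma * m_but * m_o2 * rho_diff
    o2_use = cp.beta_ox_o2_per_but * but_use
    return but_use, o2_use, sigma


# ---------------------------------------------------------------------------
# cell dynamics
# ---------------------------------------------------------------------------

def _velocity(rho_tot: np.ndarray, grid: CryptGrid, cp: CryptParams) -> np.ndarray:
    """Face-centred upward velocity from crowding pressure p=(rho/cap)^2."""
    p = (rho_tot / cp.capacity) ** 2
    u = -cp.pressure_mobility * np.diff(p) / grid.dz
    # cells are produced at the base and extruded at the top: keep the
    # transport one-way (toward the top) so the base niche is not emptied
    return np.maximum(u, 0.0)


def crypt_cell_rhs(cells: np.ndarray, solutes: np.ndarray, dcs: np.ndarray,
                   prr: float, grid: CryptGrid, params: ParameterSet,
                   c_h2s: float = 0.0) -> np.ndarray:
    """d(rho)/dt for sc, pc, gc, ent on the grid."""
    cp = params.crypt
    z, dz = grid.z, grid.dz
    sc, pc, gc, ent = cells
    rho_tot = cells.sum(axis=0) + dcs
    crowd = np.maximum(1.0 - rho_tot / cp.capacity, 0.0)
    stim = 1.0 + cp.prr_division_gain * prr

    niche = np.exp(-((z / cp.niche_width) ** 2))
    c_but = solutes[_ISOL["but"]]
    diff_zone = np.clip((z - cp.diff_zone_onset) / (1.0 - cp.diff_zone_onset), 0.0, 1.0)
    but_boost = 1.0 + cp.butyrate_diff_gain * c_but / (cp.butyrate_diff_half_sat + np.maximum(c_but, 0.0))
    delta_pc = cp.pc_differentiation * diff_zone * but_boost

    d = np.zeros_like(cells)
    # stem cells compete for niche spots (with dcs), not for the whole column
    niche_crowd = np.maximum(1.0 - (sc + dcs) / cp.niche_capacity, 0.0)
    d[0] = cp.sc_division * stim * niche * sc * niche_crowd \
        - cp.sc_to_pc * (1.0 - niche) * sc
    d[1] = (cp.sc_to_pc * (1.0 - niche) * sc
            + cp.pc_division * stim * pc * crowd - delta_pc * pc)
    d[2] = cp.goblet_fraction * delta_pc * pc - cp.diff_cell_loss * gc
    d[3] = (1.0 - cp.goblet_fraction) * delta_pc * pc - cp.diff_cell_loss * ent

    # crowding-driven upward transport (upwinded, no flux through the top
    # face) with a smooth shedding sink at the crypt mouth standing in for
    # extrusion; a small random-motility diffusion keeps fronts grid-converged
    u = _velocity(rho_tot, grid, cp)           # (n-1,) at faces
    shed = cp.shedding_rate * np.exp(-(((1.0 - z) / cp.shedding_width) ** 2))
    for k in range(4):
        rho = np.maximum(cells[k], 0.0)
        flux = u * rho[:-1]                    # upwind: donor is the lower node
        dflux = np.zeros(grid.n)
        dflux[:-1] += flux
        dflux[1:] -= flux
        d[k] -= dflux / dz
        d[k] -= shed * rho
        if cp.cell_diffusion > 0:
            lap = np.zeros(grid.n)
            lap[1:-1] = rho[2:] - 2 * rho[1:-1] + rho[:-2]
            lap[0] = 2 * (rho[1] - rho[0])          # no-flux base
            lap[-1] = 2 * (rho[-2] - rho[-1])       # no diffusive loss at top
            d[k] += cp.cell_diffusion * lap / dz**2
    return d


# ---------------------------------------------------------------------------
# solute problem
# ---------------------------------------------------------------------------

def crypt_solute_rhs(solutes: np.ndarray, cells: np.ndarray,
                     boundary: CryptBoundary, grid: CryptGrid,
                     params: ParameterSet) -> np.ndarray:
    """d(c)/dt of the five solute profiles (method of lines)."""
    cp = params.crypt
    dz = grid.dz
    gc, ent = cells[2], cells[3]
    rho_diff = gc + ent
    dcdt = np.zeros_like(solutes)

    but_use, o2_use, _ = beta_oxidation(
        solutes[_ISOL["but"]], solutes[_ISOL["O2"]], boundary.h2s, params, rho_diff)

    j0 = boundary.o2_base_flux if boundary.o2_base_flux is not None else cp.o2_base_flux

    for name in CRYPT_SOLUTES:
        i = _ISOL[name]
        c = solutes[i]
        D = cp.o2_diffusion if name == "O2" else cp.metabolite_diffusion
        lap = np.zeros_like(c)
        lap[1:-1] = (c[2:] - 2 * c[1:-1] + c[:-2]) / dz**2
        if name == "O2":
            # Neumann influx at the base, Robin exchange with inner mucus at top
            dcdt[i, 0] = 2 * D * (c[1] - c[0]) / dz**2 + 2 * j0 / dz
            out = cp.o2_top_exchange * (c[-1] - boundary.o2_inner)
            dcdt[i, -1] = 2 * D * (c[-2] - c[-1]) / dz**2 - 2 * out / dz
            dcdt[i, 1:-1] = D * lap[1:-1]
            dcdt[i] -= o2_use
        else:
            bval = getattr(boundary, name)
            lap[0] = 2 * (c[1] - c[0]) / dz**2          # no-flux base
            lap[-1] = (bval - 2 * c[-1] + c[-2]) / dz**2  # Dirichlet ghost at top
            dcdt[i] = D * lap
            sat = np.where(c > 0, c / (cp.metabolite_half_sat + c), 0.0)
            dcdt[i] -= cp.metabolite_absorption * ent * sat
            if name == "but":
                dcdt[i] -= but_use
    return dcdt


def _solve_solutes_quasi_static(cells: np.ndarray, boundary: CryptBoundary,
                                grid: CryptGrid, params: ParameterSet,
                                guess: np.ndarray | None = None,
                                iters: int = 60, tol: float = 1e-10) -> np.ndarray:
    """Steady solute profiles for frozen cells: Picard iteration on
    tridiagonal systems with lagged Monod factors."""
    cp = params.crypt
    n, dz = grid.n, grid.dz
    sol = np.zeros((5, n)) if guess is None else guess.copy()
    gc, ent = cells[2], cells[3]
    rho_diff = gc + ent
    j0 = boundary.o2_base_flux if boundary.o2_base_flux is not None else cp.o2_base_flux

    for _ in range(iters):
        prev = sol.copy()
        but_use, o2_use, _ = beta_oxidation(
            sol[_ISOL["but"]], sol[_ISOL["O2"]], boundary.h2s, params, rho_diff)

        for name in CRYPT_SOLUTES:
            i = _ISOL[name]
            D = cp.o2_diffusion if name == "O2" else cp.metabolite_diffusion
            a = D / dz**2
            lower = np.full(n, a)
            diag = np.full(n, -2 * a)
            upper = np.full(n, a)
            rhs = np.zeros(n)
            c = np.maximum(sol[i], 0.0)
            if name == "O2":
                # linearised consumption: o2_use = k_eff * c
                k_eff = np.where(c > 1e-300, o2_use / np.maximum(c, 1e-300), 0.0)
                diag -= k_eff
                # base: reflected ghost + influx
                diag[0] = -2 * a - k_eff[0]
                upper[1] = 2 * a
                rhs[0] = -2 * j0 / dz
                # top: Robin
                diag[-1] = -2 * a - k_eff[-1] - 2 * cp.o2_top_exchange / dz
                lower[-2] = 2 * a
                rhs[-1] = -2 * cp.o2_top_exchange / dz * boundary.o2_inner
            else:
                sat_lin = np.where(c > 0, 1.0 / (cp.metabolite_half_sat + c), 1.0 / cp.metabolite_half_sat)
                k_eff = cp.metabolite_absorption * ent * sat_lin
                if name == "but":
                    k_eff = k_eff + np.where(c > 1e-300,
                                             but_use / np.maximum(c, 1e-300), 0.0)
                diag -= k_eff
                diag[0] = -2 * a - k_eff[0]
                upper[1] = 2 * a
                bval = getattr(boundary, name)
                rhs[-1] = -a * bval
                diag[-1] = -2 * a - k_eff[-1]
            ab = np.zeros((3, n))
            ab[0, 1:] = upper[1:]
            ab[1] = diag
            ab[2, :-1] = lower[:-1]
            sol[i] = solve_banded((1, 1), ab, rhs)
        sol = np.maximum(sol, 0.0)
        if np.abs(sol - prev).max() <= tol * (1.0 + np.abs(sol).max()):
            break
    return sol


# ---------------------------------------------------------------------------
# integration and summary
# ---------------------------------------------------------------------------

def initial_crypt(grid: CryptGrid, params: ParameterSet,
                  boundary: CryptBoundary | None = None) -> CryptState:
    """A rough developmental initial condition: stem cells at the base."""
    boundary = boundary or CryptBoundary()
    z = grid.z
    cells = np.zeros((4, grid.n))
    cells[0] = 600.0 * np.exp(-((z / 0.15) ** 2))
    cells[1] = 400.0 * np.exp(-(((z - 0.3) / 0.2) ** 2))
    cells[2] = 150.0 * np.clip(z, 0, 1)
    cells[3] = 450.0 * np.clip(z, 0, 1)
    dcs = dcs_profile(grid, params)
    solutes = _solve_solutes_quasi_static(cells, boundary, grid, params)
    return CryptState(grid, cells, dcs, solutes, boundary)


def integrate_crypt(state: CryptState, prr: float, params: ParameterSet,
                    t_max: float | None = None, quasi_static: bool | None = None
                    ) -> tuple[CryptState, dict]:
    """Relax the crypt to stationarity under fixed boundary forcing.

    Default mode alternates quasi-static solute solves (diffusion is fast
    against cell turnover) with chunks of cell integration; the fully
    dynamic mode integrates cells and solutes jointly and exists as a
    verification path.
    """
    sp = params.solver
    cp = params.crypt
    qs = cp.quasi_static_solutes if quasi_static is None else quasi_static
    t_max = sp.crypt_t_max if t_max is None else t_max
    grid, boundary, dcs = state.grid, state.boundary, state.dcs
    cells = state.cells.copy()
    solutes = state.solutes.copy()
    n = grid.n

    if qs:
        def rhs(t, y):
            cell = np.maximum(y.reshape(4, n), 0.0)
            return crypt_cell_rhs(cell, solutes, dcs, prr, grid, params,
                                  boundary.h2s).ravel()
    else:
        def rhs(t, y):
            cell = np.maximum(y[:4 * n].reshape(4, n), 0.0)
            sol = np.maximum(y[4 * n:].reshape(5, n), 0.0)
            dc = crypt_cell_rhs(cell, sol, dcs, prr, grid, params, boundary.h2s)
            ds = crypt_solute_rhs(sol, cell, boundary, grid, params)
            return np.concatenate([dc.ravel(), ds.ravel()])

    t = 0.0
    converged = False
    res = np.inf
    while t < t_max - 1e-9:
        if qs:
            solutes = _solve_solutes_quasi_static(cells, boundary, grid, params,
                                                  guess=solutes)
            y0 = cells.ravel()
        else:
            y0 = np.concatenate([cells.ravel(), solutes.ravel()])
        t_next = min(t + sp.crypt_t_chunk, t_max)
        sol = solve_ivp(rhs, (t, t_next), y0, method="LSODA",
                        rtol=1e-6, atol=1e-6)
        if not sol.success:
            raise RuntimeError(f"crypt integrator failed: {sol.message}")
        y, t = sol.y[:, -1], sol.t[-1]
        if qs:
            cells = np.maximum(y.reshape(4, n), 0.0)
            solutes = _solve_solutes_quasi_static(cells, boundary, grid, params,
                                                  guess=solutes)
            dcell = crypt_cell_rhs(cells, solutes, dcs, prr, grid, params, boundary.h2s)
            res = float(np.abs(dcell).max() / (np.abs(cells).max() + 1e-12))
        else:
            cells = np.maximum(y[:4 * n].reshape(4, n), 0.0)
            solutes = np.maximum(y[4 * n:].reshape(5, n), 0.0)
            res = float(np.abs(rhs(t, y)).max() / (np.abs(y).max() + 1e-12))
        if res < sp.crypt_stationarity_tol:
            converged = True
            break
    out = CryptState(grid, cells, dcs, solutes, boundary)
    return out, {"converged": converged, "t_final": t, "residual": res}


def crypt_summary(state: CryptState, params: ParameterSet) -> CryptSummary:
    """Counts, gradients and fluxes of a (steady) crypt state."""
    z = state.grid.z
    cp = params.crypt
    counts = {name: float(np.trapezoid(state.cells[k], z))
              for k, name in enumerate(CELL_TYPES)}
    counts["dcs"] = float(np.trapezoid(state.dcs, z))
    o2 = state.solutes[_ISOL["O2"]]
    top = max(float(o2[-1]), 1e-300)
    flux = cp.o2_top_exchange * (o2[-1] - state.boundary.o2_inner) * cp.o2_per_cell_to_units
    base_conc = {name: float(state.solutes[_ISOL[name]][0])
                 for name in CRYPT_SOLUTES}
    gc, ent = counts["gc"], counts["ent"]
    return CryptSummary(
        counts=counts,
        total_cells=sum(counts[c] for c in CELL_TYPES),
        proliferative_cells=counts["sc"] + counts["pc"],
        differentiated_cells=gc + ent,
        goblet_to_enterocyte=gc / ent if ent > 0 else 0.0,
        o2_base_to_top=float(o2[0]) / top,
        o2_top_flux_per_crypt=float(max(flux, 0.0)),
        base_concentrations=base_conc,
    )
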