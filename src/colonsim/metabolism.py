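"""Microbial metabolism as Petersen stoichiometry plus kinetic rate vectors.

Every transformation — fermentation, sulfidogenesis, hydrolysis, bacterial
death, H2S attack on mucus and liquid-to-gas transfer — is one column of a
pair of Petersen matrices: ``P_f`` (solid volume-fraction yields) and
``P_c`` (dissolved yields, mM per unit process rate).  Source terms are then
matrix-vector products ``F = P_f @ K`` and ``C = P_c @ K`` with the kinetic
rate vector ``K`` evaluated from the current state.

Volume conservation of the mixture phase is built in: the liquid row of
``P_f`` is *computed* as minus the sum of every other row, so each column
sums to zero exactly — growth consumes liquid, lysis and degradation release
it.

Kinetic convention: biotic rates are
``q_max * f_group * prod(Monod saturations) * I_pH (methanogenesis only)
* liquid-availability factor``; the rate variable is the uptake of the
process's principal substrate (mM/h for dissolved substrates,
volume-fraction/h for solid ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ParameterSet
from .registry import (BACTERIA, COMPARTMENTS, GASES, ID, IV, IX, N_D, N_V,
                       SENSITIVITY)


class StoichiometryError(ValueError):
    """A process's yields cannot be balanced by the liquid row."""


@dataclass(frozen=True)
class ProcessSpec:
    """One metabolic/abiotic process (one Petersen column)."""

    name: str
    group: str | None                    # acting group, or None for abiotic
    compartments: tuple[str, ...]        # where the column is nonzero
    f_yields: dict[str, float]           # solid yields, liquid excluded
    c_yields: dict[str, float]           # dissolved yields (mM per rate unit)
    kinetic: str                         # human-readable rate descriptor
    # machine rate descriptor, consumed by ProcessNetwork._rates
    rate_kind: str = "growth"            # growth | hydrolysis | death | h2s_attack | gas | amp_decay
    prefactor: float = 0.0
    linear_f: int = -1                   # rate proportional to this solid fraction
    solute_monod: tuple[tuple[int, float], ...] = ()
    solid_monod: tuple[tuple[int, float], ...] = ()
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.f_yields, self.c_yields):
            for k, v in d.items():
                if not math.isfinite(v):
                    raise StoichiometryError(f"{self.name}: non-finite yield for {k}")
        if "l" in self.f_yields:
            raise StoichiometryError(
                f"{self.name}: the liquid yield is computed, not configured")


@dataclass(frozen=True)
class PetersenMatrices:
    """Stoichiometric matrices of one compartment."""

    compartment: str
    P_f: np.ndarray          # (|V|, n_processes)
    P_c: np.ndarray          # (|D|, n_processes)
    process_names: tuple[str, ...]


# ---------------------------------------------------------------------------
# rate helper forms
# ---------------------------------------------------------------------------

def ipH_factor(ph: float, params: ParameterSet) -> float:
    """Dimensionless pH gate on methanogenesis: 1 at the optimum, -> 0 away.

    A Gaussian bell in pH with width ``ph_sigma``; its half-value points sit
    at ``opt +- sigma * sqrt(2 ln 2)``.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    m = params.metabolism
    return math.exp(-((ph - m.ph_opt_methanogenesis) ** 2) / (2 * m.ph_sigma**2))


def death_rate(group: str, c_amp: float, c_o2: float, params: ParameterSet) -> float:
    """Per-capita death rate (1/h): basal + AMP term + class-weighted O2 term.

    Oxygen acts as an inflammation proxy; the delta class has a null O2
    coefficient (tolerant or inflammation-promoted groups).
    """
    if group not in SENSITIVITY:
        raise KeyError(f"unknown microbial group {group!r}")
    if c_amp < 0 or c_o2 < 0:
        raise ValueError("concentrations must be non-negative")
    d = params.death
    return d.basal + d.amp_coeff * c_amp + d.o2_coeff(group) * c_o2


def _smooth_ramp(x: float | np.ndarray, s: float):
    """C1 ramp: 0 for x<=0, quadratic blend on (0, s), x - s/2 beyond."""
    x = np.asarray(x, dtype=float)
    out = np.where(x <= 0, 0.0, np.where(x < s, x * x / (2 * s), x - s / 2))
    return out if out.ndim else float(out)


def h2s_mucus_attack(c_h2s: float, f_m: float, params: ParameterSet) -> float:
    """Mucus-degradation rate (volume fraction / h) from H2S toxicity.

    Zero below the concentration threshold, then grows ~linearly with the
    excess concentration and proportionally to the local mucus fraction.
    The degraded mucus volume is released as liquid (Petersen column).
    """
    if c_h2s < 0 or f_m < 0:
        raise ValueError("inputs must be non-negative")
    t = params.h2s_toxicity
    return t.rate * _smooth_ramp(c_h2s - t.threshold, t.smoothness) * f_m


def gas_liquid_transfer(c_g: float, gas: str, params: ParameterSet) -> float:
    """Liquid-to-gas sink rate (mM/h) for one of CH4, CO2, H2, H2S.

    First-order transfer toward the per-gas equilibrium concentration;
    strictly a sink (zero below equilibrium). Oxygen is never transferred.
    """
    if gas not in GASES:
        raise ValueError(f"{gas!r} is not a transferable gas (O2 is a solute)")
    if c_g < 0:
        raise ValueError("concentration must be non-negative")
    g = params.gas_transfer
    return g.k_la[gas] * max(c_g - g.c_eq[gas], 0.0)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _build_processes(params: ParameterSet) -> list[ProcessSpec]:
    m = params.metabolism
    iph = ipH_factor(m.ph, params)
    kl = m.liquid_half_sat
    il = IV["l"]

    procs: list[ProcessSpec] = []

    def growth_solute(name, group, sub, y_products, uptake, extra_monod=(), gate=1.0,
                      kinetic=""):
        """Dissolved principal substrate; biomass from liquid volume."""
        yb = uptake.yield_biomass / m.nu_v
        cy = {sub: -1.0}
        cy.update(y_products)
        procs.append(ProcessSpec(
            name=name, group=group, compartments=("L", "O"),
            f_yields={group: yb},
            c_yields=cy,
            kinetic=kinetic or f"{uptake.q_max:g}*f_{group}*M({sub},{uptake.half_sat:g})",
            rate_kind="growth", prefactor=uptake.q_max * gate,
            linear_f=IV[group],
            solute_monod=((ID[sub], uptake.half_sat),) + tuple(extra_monod),
            solid_monod=((il, kl),),
        ))

    def growth_solid(name, group, sub, yb, c_yields, comps, q_max, half_sat,
                     extra_monod=()):
        """Solid principal substrate (prot or m); excess volume -> liquid."""
        procs.append(ProcessSpec(
            name=name, group=group, compartments=comps,
            f_yields={sub: -1.0, group: yb},
            c_yields=dict(c_yields),
            kinetic=f"{q_max:g}*f_{group}*M(f_{sub},{half_sat:g})",
            rate_kind="growth", prefactor=q_max,
            linear_f=IV[group],
            solute_monod=tuple(extra_monod),
            solid_monod=((IV[sub], half_sat), (il, kl)),
        ))

    # --- hydrolysis ---------------------------------------------------------
    for g in ("Bmon_phi", "Bmon_mu"):
        procs.append(ProcessSpec(
            name=f"hyd_pol_{g}", group=g, compartments=("L",),
            f_yields={"pol": -1.0},
            c_yields={"mon": m.mon_yield_pol * m.nu_v},
            kinetic=f"{m.k_hyd_pol:g}*f_pol*M(f_{g},{m.hyd_group_half_sat:g})",
            rate_kind="hydrolysis", prefactor=m.k_hyd_pol,
            linear_f=IV["pol"],
            solid_monod=((IV[g], m.hyd_group_half_sat), (il, kl)),
        ))
        procs.append(ProcessSpec(
            name=f"hyd_muc_{g}", group=g, compartments=("O",),
            f_yields={"m": -1.0},
            c_yields={"mon": m.mon_yield_mucus * m.nu_v},
            kinetic=f"{m.k_hyd_mucus:g}*f_m*M(f_{g},{m.hyd_group_half_sat:g})",
            rate_kind="hydrolysis", prefactor=m.k_hyd_mucus,
            linear_f=IV["m"],
            solid_monod=((IV[g], m.hyd_group_half_sat), (il, kl)),
        ))

    # --- monosaccharide fermentation ----------------------------------------
    for g in ("Bmon_phi", "Bmon_mu"):
        growth_solute(
            f"ferm_mon_{g}", g, "mon",
            {"la": m.y_mon_la, "ac": m.y_mon_ac, "pro": m.y_mon_pro,
             "but": m.y_mon_but, "H2": m.y_mon_h2, "CO2": m.y_mon_co2},
            m.mon_uptake)

    # --- lactate fermentation / oxidation -----------------------------------
    for g in ("Bla_phi", "Bla_mu", "Bla_delta"):
        growth_solute(
            f"ferm_la_{g}", g, "la",
            {"ac": m.y_la_ac, "pro": m.y_la_pro, "but": m.y_la_but,
             "H2": m.y_la_h2, "CO2": m.y_la_co2},
            m.la_uptake)
    growth_solute(
        "oxid_la_Bla_delta", "Bla_delta", "la",
        {"ac": m.y_la_ox_ac, "CO2": m.y_la_ox_co2, "O2": -m.y_la_ox_o2},
        m.la_ox_uptake, extra_monod=((ID["O2"], m.k_o2_la_ox),))

    # --- hydrogenotrophs ----------------------------------------------------
    growth_solute(
        "acetogenesis_BH2a", "BH2a_phi", "H2",
        {"CO2": -0.5, "ac": m.y_h2a_ac},
        m.h2_ac_uptake, extra_monod=((ID["CO2"], 0.5),))
    growth_solute(
        "methanogenesis_BH2m", "BH2m_phi", "H2",
        {"CO2": -0.25, "CH4": m.y_h2m_ch4},
        m.h2_me_uptake, extra_monod=((ID["CO2"], 0.5),), gate=iph,
        kinetic=f"I_pH({iph:.3f})*{m.h2_me_uptake.q_max:g}*f_BH2m_phi*M(H2)")

    # --- H2S producers ------------------------------------------------------
    growth_solid(
        "sulfido_prot_BH2s", "BH2s_delta", "prot",
        yb=m.prot_uptake.yield_biomass,
        c_yields={"H2S": m.y_prot_h2s, "ac": m.y_prot_ac, "O2": -m.y_prot_o2},
        comps=("L",), q_max=m.prot_uptake.q_max, half_sat=m.prot_uptake.half_sat,
        extra_monod=((ID["O2"], m.k_o2_h2s),))
    growth_solute(
        "sulfido_h2_BH2s", "BH2s_delta", "H2",
        {"H2S": m.y_h2s_h2},
        m.h2s_h2_uptake)
    growth_solid(
        "sulfido_muc_BH2s", "BH2s_delta", "m",
        yb=m.muc_uptake.yield_biomass,
        c_yields={"H2S": m.y_muc_h2s, "O2": -m.y_muc_o2},
        comps=("O",), q_max=m.muc_uptake.q_max, half_sat=m.muc_uptake.half_sat,
        extra_monod=((ID["O2"], m.k_o2_muc),))

    # --- death (basal + AMP + class-weighted O2), lysis releases liquid ------
    for g in BACTERIA:
        procs.append(ProcessSpec(
            name=f"death_{g}", group=g, compartments=("L", "O"),
            f_yields={g: -1.0}, c_yields={},
            kinetic=f"(basal + k_AMP*c_AMP + k_O2[{SENSITIVITY[g]}]*c_O2)*f_{g}",
            rate_kind="death", extra={"o2_coeff": params.death.o2_coeff(g)},
            linear_f=IV[g]))

    # --- H2S toxicity on mucus bonds (abiotic) -------------------------------
    procs.append(ProcessSpec(
        name="h2s_mucus_attack", group=None, compartments=("O", "I"),
        f_yields={"m": -1.0}, c_yields={},
        kinetic="k_tox*ramp(c_H2S - threshold)*f_m",
        rate_kind="h2s_attack", linear_f=IV["m"]))

    # --- liquid-to-gas transfer sinks ----------------------------------------
    for gname in GASES:
        procs.append(ProcessSpec(
            name=f"gas_transfer_{gname}", group=None,
            compartments=("L", "O", "I"),
            f_yields={}, c_yields={gname: -1.0},
            kinetic=f"k_La*max(c_{gname} - c_eq, 0)",
            rate_kind="gas",
            extra={"k_la": params.gas_transfer.k_la[gname],
                   "c_eq": params.gas_transfer.c_eq[gname],
                   "c_idx": ID[gname]}))

    # --- AMP first-order loss -------------------------------------------------
    procs.append(ProcessSpec(
        name="amp_decay", group=None, compartments=("L", "O", "I"),
        f_yields={}, c_yields={"AMP": -1.0},
        kinetic="k_dec*c_AMP",
        rate_kind="amp_decay",
        extra={"k": params.secretion.amp_decay}))

    return procs


class ProcessNetwork:
    """Compiled process network: Petersen matrices and fast rate evaluation."""

    def __init__(self, params: ParameterSet):
        self.params = params
        self.processes = _build_processes(params)
        self.names = tuple(p.name for p in self.processes)
        self.n = len(self.processes)
        self._compile()

    def _compile(self) -> None:
        n = self.n
        P_f = np.zeros((3, N_V, n))
        P_c = np.zeros((3, N_D, n))
        for j, p in enumerate(self.processes):
            for xi, x in enumerate(COMPARTMENTS):
                if x not in p.compartments:
                    continue
                for comp, y in p.f_yields.items():
                    P_f[xi, IV[comp], j] = y
                for comp, y in p.c_yields.items():
                    P_c[xi, ID[comp], j] = y
                # liquid row closes the volume balance (Eq-style column sum 0)
                P_f[xi, IV["l"], j] = -P_f[xi, :, j].sum() + P_f[xi, IV["l"], j]
        if not np.allclose(P_f.sum(axis=1), 0.0, atol=1e-12):
            raise StoichiometryError("liquid-row closure failed")
        self._P_f, self._P_c = P_f, P_c

        # rate evaluation plan
        d = self.params.death
        self._death_idx = [(j, IV[p.group], p.extra["o2_coeff"])
                           for j, p in enumerate(self.processes) if p.rate_kind == "death"]
        self._death_basal = d.basal
        self._death_amp = d.amp_coeff
        self._applic = np.zeros((3, n), dtype=bool)
        for j, p in enumerate(self.processes):
            for x in p.compartments:
                self._applic[IX[x], j] = True

    def petersen(self, compartment: str) -> PetersenMatrices:
        xi = IX[compartment]
        return PetersenMatrices(compartment, self._P_f[xi].copy(),
                                self._P_c[xi].copy(), self.names)

    # -- kinetics -------------------------------------------------------------
    def rates(self, f: np.ndarray, c: np.ndarray, compartment: str) -> np.ndarray:
        """Kinetic rate vector K for one compartment.

        Infinitesimal integrator undershoots are clipped to zero here (never
        in the state itself).
        """
        floor = self.params.solver.rate_floor
        f = np.where(f > floor, f, 0.0)
        c = np.where(c > floor, c, 0.0)
        tox = self.params.h2s_toxicity
        K = np.zeros(self.n)
        c_amp = c[ID["AMP"]]
        c_o2 = c[ID["O2"]]
        for j, p in enumerate(self.processes):
            kind = p.rate_kind
            if kind in ("growth", "hydrolysis"):
                r = p.prefactor * f[p.linear_f]
                if r == 0.0:
                    continue
                for idx, k in p.solute_monod:
                    r *= c[idx] / (k + c[idx]) if c[idx] > 0 else 0.0
                for idx, k in p.solid_monod:
                    r *= f[idx] / (k + f[idx]) if f[idx] > 0 else 0.0
                K[j] = r
            elif kind == "death":
                rate = self._death_basal + self._death_amp * c_amp + p.extra["o2_coeff"] * c_o2
                K[j] = rate * f[p.linear_f]
            elif kind == "h2s_attack":
                K[j] = tox.rate * _smooth_ramp(c[ID["H2S"]] - tox.threshold,
                                               tox.smoothness) * f[p.linear_f]
            elif kind == "gas":
                K[j] = p.extra["k_la"] * max(c[p.extra["c_idx"]] - p.extra["c_eq"], 0.0)
            elif kind == "amp_decay":
                K[j] = p.extra["k"] * c_amp
        K[~self._applic[IX[compartment]]] = 0.0
        return K

    def metabolic_rhs(self, f: np.ndarray, c: np.ndarray,
                      compartment: str) -> tuple[np.ndarray, np.ndarray]:
        """Source terms (F over V, C over D) for one compartment."""
        xi = IX[compartment]
        K = self.rates(f, c, compartment)
        return self._P_f[xi] @ K, self._P_c[xi] @ K

    # -- inspection -------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        """Tabular (long) view of all yields and kinetic descriptors."""
        rows = []
        for p in self.processes:
            xi = IX[p.compartments[0]]
            j = self.names.index(p.name)
            for i, comp in enumerate(("f", "c")):
                mat = (self._P_f, self._P_c)[i][xi][:, j]
                names = (list(IV), list(ID))[i]
                for comp_name, y in zip(names, mat):
                    if y != 0.0:
                        rows.append({"process": p.name, "group": p.group or "",
                                     "phase": comp, "component": comp_name,
                                     "yield": y, "kinetic": p.kinetic,
                                     "compartments": "+".join(p.compartments)})
        return pd.DataFrame(rows)


# functional wrappers matching the module surface ---------------------------

def build_petersen_matrices(params: ParameterSet, compartment: str) -> PetersenMatrices:
    return ProcessNetwork(params).petersen(compartment)


def kinetic_rates(f: np.ndarray, c: np.ndarray, params: ParameterSet,
                  compartment: str, network: ProcessNetwork | None = None) -> np.ndarray:
    net = network or ProcessNetwork(params)
    return net.rates(np.asarray(f, float), np.asarray(c, float), compartment)


def metabolic_rhs(f: np.ndarray, c: np.ndarray, params: ParameterSet,
                  compartment: str, network: ProcessNetwork | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    net = network or ProcessNetwork(params)
    return net.metabolic_rhs(np.asarray(f, float), np.asarray(c, float), compartment)
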