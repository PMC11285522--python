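"""Model configuration: geometry, kinetic parameters and diet specifications.

Everything tunable lives in :class:`ParameterSet`, a validated, YAML/JSON
round-trippable document (``schema_version`` keyed).  Units follow a fixed
convention: lengths cm, volumes cm3, time h, concentrations mM, oxygen in
arbitrary units.  Default values are *calibrated* repo defaults (chosen so
the reference simulation lands in the physiological ranges discussed in
docs/methods.md), not transcriptions of a published table.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .registry import GASES, REGISTRY, SENSITIVITY, SetsRegistry

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CompartmentGeometry(_Strict):
    """Cylindrical colon-section geometry.

    The section (length ``length``, radius ``radius``) is split radially into
    lumen, outer mucus and inner mucus shells; the two mucus shells share the
    total mucus thickness.  All volumes are constant over a simulation.
    """

    length: float = Field(1.0, gt=0, description="section length Lsec (cm)")
    radius: float = Field(2.5, gt=0, description="section radius R (cm)")
    inner_mucus_thickness: float = Field(0.04, gt=0)
    outer_mucus_thickness: float = Field(0.04, gt=0)
    crypts_per_section: float = Field(1.5e5, gt=0)

    @model_validator(mode="after")
    def _thin_mucus(self) -> "CompartmentGeometry":
        if self.inner_mucus_thickness + self.outer_mucus_thickness >= self.radius:
            raise ValueError("mucus layers thicker than the section radius")
        return self

    # derived quantities -----------------------------------------------------
    @property
    def lumen_radius(self) -> float:
        return self.radius - self.inner_mucus_thickness - self.outer_mucus_thickness

    @property
    def volume_L(self) -> float:
        return math.pi * self.lumen_radius**2 * self.length

    @property
    def volume_O(self) -> float:
        r_in = self.lumen_radius
        r_out = r_in + self.outer_mucus_thickness
        return math.pi * (r_out**2 - r_in**2) * self.length

    @property
    def volume_I(self) -> float:
        r_in = self.lumen_radius + self.outer_mucus_thickness
        return math.pi * (self.radius**2 - r_in**2) * self.length

    @property
    def area_gamma_L(self) -> float:
        """Lumen / outer-mucus interface area (cm2)."""
        return 2 * math.pi * self.lumen_radius * self.length

    @property
    def area_gamma_O(self) -> float:
        """Outer / inner mucus interface area (cm2)."""
        return 2 * math.pi * (self.lumen_radius + self.outer_mucus_thickness) * self.length

    @property
    def area_gamma_I(self) -> float:
        """Inner mucus / epithelium interface area (cm2)."""
        return 2 * math.pi * self.radius * self.length

    @property
    def area_in(self) -> float:
        """Lumen cross-section at the input surface Gamma_in (cm2)."""
        return math.pi * self.lumen_radius**2

    @property
    def area_out(self) -> float:
        return self.area_in

    def volumes(self) -> tuple[float, float, float]:
        return self.volume_L, self.volume_O, self.volume_I


class DietInput(_Strict):
    """Fibre/protein volume fractions and dissolved inputs at Gamma_in."""

    f_pol_in: float = Field(ge=0)
    f_prot_in: float = Field(ge=0)
    c_mon_in: float = Field(ge=0, description="mM")
    c_la_in: float = Field(ge=0)
    c_ac_in: float = Field(ge=0)
    c_pro_in: float = Field(ge=0)
    c_but_in: float = Field(ge=0)
    v_in: float = Field(0.416, gt=0, description="transit inflow (cm/h)")

    @model_validator(mode="after")
    def _fractions(self) -> "DietInput":
        if self.f_pol_in + self.f_prot_in >= 1:
            raise ValueError("fibre + protein volume fractions must be < 1")
        return self


class TransitParams(_Strict):
    """Longitudinal transit; only bacteria resist washout."""

    retention_max: float = Field(0.3, ge=0, lt=1,
                                 description="max fraction of outflow resisted by a group")
    retention_half_sat: float = Field(5e-4, gt=0,
                                      description="group fraction at half retention")


class SecretionParams(_Strict):
    """Epithelial secretion of mucus, AMPs and oxygen into the inner mucus."""

    mucus_per_goblet: float = Field(1.4e-9, ge=0,
                                    description="basal mucus volume per goblet cell (cm3/h)")
    mucus_prr_gain: float = Field(1.5, ge=0,
                                  description="fold increase of mucus secretion at full PRR activation")
    amp_per_cell: float = Field(1.4e-10, ge=0,
                                description="basal AMP output per differentiated cell (mmol-equivalent/h)")
    amp_prr_gain: float = Field(4.0, ge=0)
    amp_decay: float = Field(0.08, ge=0, description="first-order AMP loss (1/h)")


class AbsorptionParams(_Strict):
    """Enterocyte-driven uptake of SCFAs, lactate, H2S and liquid.

    Metabolites are routed lumen/outer-mucus -> inner mucus -> epithelium;
    liquid is removed compartment-wise.  Rates scale linearly with the
    enterocyte count relative to ``n_ent_ref``.
    """

    n_ent_ref: float = Field(1200.0, gt=0, description="reference enterocytes per crypt")
    metabolite_rate_L: float = Field(0.15, ge=0, description="1/h at reference cellularity")
    metabolite_rate_O: float = Field(0.45, ge=0)
    metabolite_rate_I: float = Field(13.0, ge=0)
    liquid_rate_L: float = Field(0.03, ge=0)
    liquid_rate_O: float = Field(0.04, ge=0)
    liquid_rate_I: float = Field(0.05, ge=0)

    @model_validator(mode="after")
    def _ordering(self) -> "AbsorptionParams":
        if not (self.metabolite_rate_I > self.metabolite_rate_O > self.metabolite_rate_L):
            raise ValueError("absorption rates must intensify toward the wall (I > O > L)")
        if not (self.liquid_rate_I > self.liquid_rate_O > self.liquid_rate_L):
            raise ValueError("liquid absorption rates must intensify toward the wall")
        return self


class DiffusionParams(_Strict):
    """Passive inter-compartment exchange coefficients (cm/h) per solute."""

    mon: float = Field(0.03, ge=0)
    CH4: float = Field(0.05, ge=0)
    CO2: float = Field(0.05, ge=0)
    H2: float = Field(0.08, ge=0)
    H2S: float = Field(0.03, ge=0)
    O2: float = Field(0.02, ge=0)
    AMP: float = Field(0.004, ge=0)


class MotilityParams(_Strict):
    """Active attraction of bacteria toward the outer mucus."""

    attraction_velocity: float = Field(4e-2, ge=0, description="cm/h")
    mucus_half_sat: float = Field(0.05, gt=0,
                                  description="outer-mucus mucus fraction at half attraction")


class GrowthParams(_Strict):
    """One substrate-uptake process: rate = q_max * f_group * prod(sat)."""

    q_max: float = Field(gt=0, description="max substrate uptake (mM/h per unit group fraction)")
    half_sat: float = Field(gt=0, description="substrate half-saturation (mM or fraction)")
    yield_biomass: float = Field(ge=0, description="biomass volume per substrate volume-equivalent")


class MetabolismParams(_Strict):
    """Kinetics and yields of the fermentation / sulfidogenesis network.

    ``nu_v`` converts dissolved amounts (mM) to mixture volume fractions for
    the bookkeeping between dissolved substrates and biomass volume.
    Product yields are mM per mM of substrate taken up.  All values are
    calibrated defaults.
    """

    nu_v: float = Field(5000.0, gt=0, description="mM per unit volume fraction")
    liquid_half_sat: float = Field(0.05, gt=0,
                                   description="liquid fraction at half growth limitation")

    # polysaccharide / mucus hydrolysis (volume-fraction kinetics)
    k_hyd_pol: float = Field(2.0, ge=0, description="1/h")
    k_hyd_mucus: float = Field(0.4, ge=0)
    hyd_group_half_sat: float = Field(5e-4, gt=0)
    mon_yield_pol: float = Field(0.55, ge=0, description="fraction of hydrolysed volume -> mon")
    mon_yield_mucus: float = Field(0.03, ge=0)

    # monosaccharide fermenters
    mon_uptake: GrowthParams = GrowthParams(q_max=60000.0, half_sat=2.0, yield_biomass=0.05)
    y_mon_la: float = 0.35
    y_mon_ac: float = 0.33
    y_mon_pro: float = 0.125
    y_mon_but: float = 0.125
    y_mon_h2: float = 0.80
    y_mon_co2: float = 0.80

    # lactate fermenters (phi, mu and the fermentative pathway of delta)
    la_uptake: GrowthParams = GrowthParams(q_max=70000.0, half_sat=1.0, yield_biomass=0.03)
    y_la_ac: float = 0.60
    y_la_pro: float = 0.45
    y_la_but: float = 0.45
    y_la_h2: float = 0.30
    y_la_co2: float = 0.25

    # oxidative lactate pathway (Bla_delta only; consumes O2)
    la_ox_uptake: GrowthParams = GrowthParams(q_max=30000.0, half_sat=1.0, yield_biomass=0.035)
    k_o2_la_ox: float = Field(0.8, gt=0, description="O2 half-sat (arb. units)")
    y_la_ox_ac: float = 0.55
    y_la_ox_co2: float = 0.9
    y_la_ox_o2: float = Field(0.8, ge=0, description="O2 consumed per lactate oxidised")

    # hydrogenotrophs
    h2_ac_uptake: GrowthParams = GrowthParams(q_max=70000.0, half_sat=0.2, yield_biomass=0.018)
    y_h2a_ac: float = 0.25
    y_h2a_co2: float = 0.5
    h2_me_uptake: GrowthParams = GrowthParams(q_max=80000.0, half_sat=0.15, yield_biomass=0.0008)
    y_h2m_ch4: float = 0.25
    y_h2m_co2: float = 0.25
    ph: float = Field(6.8, ge=0, le=14, description="constant compartment pH")
    ph_opt_methanogenesis: float = Field(7.0, ge=0, le=14)
    ph_sigma: float = Field(1.0, gt=0, description="width of the I_pH bell (pH units)")

    # H2S producers: dietary-protein, hydrogen and mucoprotein pathways.
    # The group relies on oxidative pathways, hence the larger division rate
    # (expressed through larger yields/uptakes) and the O2 dependence.
    prot_uptake: GrowthParams = GrowthParams(q_max=6.0, half_sat=0.03, yield_biomass=0.035)
    k_o2_h2s: float = Field(0.02, gt=0, description="O2 half-sat of the protein pathway")
    y_prot_h2s: float = Field(400.0, ge=0, description="mM H2S per unit protein volume")
    y_prot_ac: float = Field(150.0, ge=0)
    y_prot_o2: float = Field(10.0, ge=0)
    h2s_h2_uptake: GrowthParams = GrowthParams(q_max=10000.0, half_sat=0.3, yield_biomass=0.002)
    y_h2s_h2: float = Field(0.05, ge=0, description="mM H2S per mM H2")
    muc_uptake: GrowthParams = GrowthParams(q_max=0.3, half_sat=0.08, yield_biomass=0.02)
    k_o2_muc: float = Field(0.05, gt=0)
    y_muc_h2s: float = Field(12.0, ge=0, description="mM H2S per unit mucus volume")
    y_muc_o2: float = Field(6.0, ge=0)

    @model_validator(mode="after")
    def _mucoprotein_is_poorer(self) -> "MetabolismParams":
        # the mucoprotein pathway must yield less biomass and less H2S per
        # unit substrate volume than the dietary-protein pathway
        if self.muc_uptake.yield_biomass >= self.prot_uptake.yield_biomass:
            raise ValueError("mucoprotein pathway must yield less biomass than dietary protein")
        if self.y_muc_h2s >= self.y_prot_h2s:
            raise ValueError("mucoprotein pathway must yield less H2S than dietary protein")
        return self


class DeathParams(_Strict):
    """Basal, AMP-dependent and oxygen-dependent (sensitivity class) death."""

    basal: float = Field(0.02, ge=0, description="1/h")
    amp_coeff: float = Field(0.3, ge=0, description="1/h per mM AMP")
    o2_coeff_phi: float = Field(0.08, ge=0, description="1/h per O2 unit")
    o2_coeff_mu: float = Field(0.02, ge=0)
    o2_coeff_delta: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _ordering(self) -> "DeathParams":
        if not (self.o2_coeff_phi >= self.o2_coeff_mu >= self.o2_coeff_delta):
            raise ValueError("oxygen sensitivity must be ordered phi >= mu >= delta")
        return self

    def o2_coeff(self, group: str) -> float:
        cls = SENSITIVITY[group]
        return {"phi": self.o2_coeff_phi, "mu": self.o2_coeff_mu,
                "delta": self.o2_coeff_delta}[cls]


class H2SToxicityParams(_Strict):
    """H2S attack on mucus bonds above a concentration threshold."""

    threshold: float = Field(1.0, ge=0, description="mM; healthy levels stay below")
    rate: float = Field(0.4, ge=0, description="1/h per mM above threshold")
    smoothness: float = Field(0.05, gt=0, description="softplus width (mM)")


class GasTransferParams(_Strict):
    """First-order liquid-to-gas sinks for CH4, CO2, H2 and H2S."""

    k_la: dict[str, float] = Field(
        default_factory=lambda: {"CH4": 0.6, "CO2": 0.6, "H2": 1.2, "H2S": 0.25})
    c_eq: dict[str, float] = Field(
        default_factory=lambda: {"CH4": 0.0, "CO2": 2.0, "H2": 0.0, "H2S": 0.0})

    @model_validator(mode="after")
    def _gases_only(self) -> "GasTransferParams":
        for d in (self.k_la, self.c_eq):
            bad = set(d) - set(GASES)
            if bad:
                raise ValueError(f"gas transfer defined for non-gas species: {sorted(bad)}")
            if set(d) != set(GASES):
                raise ValueError("gas transfer must cover exactly CH4, CO2, H2, H2S")
            if any(v < 0 for v in d.values()):
                raise ValueError("gas-transfer constants must be non-negative")
        return self


class CryptParams(_Strict):
    """Crypt cell-population and solute-diffusion parameters.

    The crypt axis is normalised to [0, 1]; densities are cells per unit
    normalised length, so cell counts are integrals over [0, 1].
    Defaults are calibrated to human-crypt magnitudes (total ~2200 cells,
    goblet:enterocyte ~ 1:3, base-to-top O2 ratio ~7).
    """

    n_nodes: int = Field(50, ge=8)
    capacity: float = Field(3000.0, gt=0, description="total-density carrying capacity")
    pressure_mobility: float = Field(0.1, gt=0, description="crowding-driven motility")
    cell_diffusion: float = Field(1e-3, ge=0,
                                  description="random cell motility on the unit axis (1/h)")

    sc_division: float = Field(0.8, ge=0, description="1/h, in-niche stem division")
    niche_capacity: float = Field(1600.0, gt=0,
                                  description="sc+dcs density the niche supports")
    shedding_rate: float = Field(0.3, ge=0,
                                 description="1/h cell shedding at the crypt mouth")
    shedding_width: float = Field(0.06, gt=0,
                                  description="width of the shedding zone below z=1")
    sc_to_pc: float = Field(0.4, ge=0, description="1/h, out-of-niche commitment")
    niche_width: float = Field(0.1, gt=0)
    pc_division: float = Field(0.22, ge=0)
    pc_differentiation: float = Field(0.35, ge=0, description="1/h baseline pc -> gc/ent")
    diff_zone_onset: float = Field(0.1, ge=0, lt=1)
    goblet_fraction: float = Field(0.25, ge=0, le=1, description="gc share of pc fate (1:3 gc:ent)")
    diff_cell_loss: float = Field(0.0033, ge=0, description="1/h turnover of gc/ent")
    prr_division_gain: float = Field(0.6, ge=0, description="division amplification at full PRR")
    butyrate_diff_gain: float = Field(1.0, ge=0, description="differentiation boost by butyrate")
    butyrate_diff_half_sat: float = Field(3.0, gt=0, description="mM")

    dcs_count: float = Field(60.0, ge=0)
    dcs_width: float = Field(0.08, gt=0)
    dcs_cutoff: float = Field(0.25, gt=0, le=1)

    # solutes along the crypt
    o2_diffusion: float = Field(3e-3, gt=0, description="1/h on the unit axis")
    o2_base_flux: float = Field(0.13, ge=0, description="O2 influx at z=0 (units/h)")
    o2_top_exchange: float = Field(0.06, ge=0, description="Robin constant at z=1")
    o2_consumption: float = Field(2.2e-4, ge=0, description="per differentiated cell, 1/h")
    o2_half_sat: float = Field(5.0, gt=0, description="arb. units")
    metabolite_diffusion: float = Field(0.012, gt=0)
    metabolite_absorption: float = Field(6e-5, ge=0, description="per enterocyte, 1/h")
    metabolite_half_sat: float = Field(5.0, gt=0, description="mM")
    beta_ox_rate: float = Field(1.3e-5, ge=0, description="butyrate use per diff cell (mM/h)")
    beta_ox_o2_per_but: float = Field(2.0, ge=0, description="O2 consumed per butyrate oxidised")
    but_switch_half_sat: float = Field(1.2, gt=0, description="mM butyrate at half activation")
    h2s_switch_threshold: float = Field(1.0, gt=0, description="mM H2S at half inhibition")
    h2s_switch_hill: float = Field(4.0, gt=0)

    prr_half_sat: float = Field(0.013, gt=0, description="f_B^O at half PRR activation")
    prr_hill: float = Field(1.0, gt=0)

    o2_per_cell_to_units: float = Field(8e-5, gt=0, description="crypt-top flux -> units*cm3/h")
    quasi_static_solutes: bool = True


class SolverParams(_Strict):
    ode_method: Literal["LSODA", "BDF", "Radau"] = "LSODA"
    rtol: float = Field(1e-7, gt=0)
    atol_fraction: float = Field(1e-10, gt=0)
    atol_concentration: float = Field(1e-8, gt=0)
    t_max: float = Field(400.0, gt=0, description="h; per-section horizon")
    t_chunk: float = Field(100.0, gt=0, description="h between stationarity checks")
    stationarity_tol: float = Field(1e-8, gt=0)
    rate_floor: float = Field(1e-13, gt=0, description="negative-undershoot clip in rates")
    crypt_t_max: float = Field(2000.0, gt=0)
    crypt_t_chunk: float = Field(200.0, gt=0)
    crypt_stationarity_tol: float = Field(1e-7, gt=0)
    coupling_relaxation: float = Field(0.5, gt=0, le=1)
    coupling_tol: float = Field(3e-4, gt=0)
    coupling_max_iter: int = Field(25, ge=1)


class InoculumParams(_Strict):
    """Composition of the non-diet part of the first section's input."""

    f_bact_in: float = Field(2.5e-4, ge=0, description="per-group seed fraction at Gamma_in")
    f_residual_in: float = Field(0.10, ge=0)
    c_o2_in: float = Field(0.1, ge=0, description="arb. units")


class ParameterSet(_Strict):
    """Complete, validated model parameterisation."""

    schema_version: int = SCHEMA_VERSION
    geometry: CompartmentGeometry = Field(default_factory=CompartmentGeometry)
    transit: TransitParams = Field(default_factory=TransitParams)
    secretion: SecretionParams = Field(default_factory=SecretionParams)
    absorption: AbsorptionParams = Field(default_factory=AbsorptionParams)
    diffusion: DiffusionParams = Field(default_factory=DiffusionParams)
    motility: MotilityParams = Field(default_factory=MotilityParams)
    metabolism: MetabolismParams = Field(default_factory=MetabolismParams)
    death: DeathParams = Field(default_factory=DeathParams)
    h2s_toxicity: H2SToxicityParams = Field(default_factory=H2SToxicityParams)
    gas_transfer: GasTransferParams = Field(default_factory=GasTransferParams)
    crypt: CryptParams = Field(default_factory=CryptParams)
    solver: SolverParams = Field(default_factory=SolverParams)
    inoculum: InoculumParams = Field(default_factory=InoculumParams)

    @model_validator(mode="after")
    def _schema(self) -> "ParameterSet":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        return self


class ConfigurationError(ValueError):
    """Raised when a configuration document cannot be validated."""


def default_config() -> ParameterSet:
    """The shipped calibrated default parameterisation."""
    return ParameterSet()


def load_config(source: str | Path | dict) -> tuple[ParameterSet, CompartmentGeometry, SetsRegistry]:
    """Load and validate a configuration document (YAML/JSON path or mapping).

    Returns the validated parameter set, its geometry, and the (fixed)
    component registry.  Unknown keys are rejected with their paths; missing
    keys fall back to shipped defaults only at the group level — a partial
    document overrides whole groups.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except OSError as exc:
            raise ConfigurationError(f"cannot read configuration: {exc}") from exc
    else:
        raw = source
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration document must be a mapping")
    try:
        params = ParameterSet.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors())
        raise ConfigurationError(f"invalid configuration ({paths})") from exc
    return params, params.geometry, REGISTRY


def save_config(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a canonical YAML document."""
    doc = params.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# --------------------------------------------------------------------------
# Diets
# --------------------------------------------------------------------------

#: fibre volume-fraction scan range and the matching dissolved-input ranges (mM)
FIBRE_RANGE = (0.02, 0.06)
PROTEIN_RANGE = (0.01, 0.03)
_METABOLITE_RANGES: dict[str, tuple[float, float]] = {
    "mon": (1e-5, 4e-5),
    "la": (2.5e-6, 5.5e-6),
    "ac": (3e-5, 7e-5),
    "pro": (1e-5, 2.5e-5),
    "but": (5e-6, 2.5e-5),
}


def reference_diet() -> DietInput:
    """The healthy reference diet (high fibre, normal protein)."""
    return DietInput(
        f_pol_in=0.05, f_prot_in=0.0135,
        c_mon_in=3.33e-5, c_la_in=3e-6, c_ac_in=6e-5,
        c_pro_in=2e-5, c_but_in=2e-5,
    )


def hplf_diet() -> DietInput:
    """The high-protein / low-fibre diet."""
    return DietInput(
        f_pol_in=0.025, f_prot_in=0.025,
        c_mon_in=1.25e-5, c_la_in=3.125e-6, c_ac_in=3.75e-5,
        c_pro_in=1.25e-5, c_but_in=6.25e-6,
    )


def diet_from_fibre_protein(f_pol: float, f_prot: float, v_in: float = 0.416) -> DietInput:
    """Grid-scan diet: dissolved inputs scale affinely with the fibre fraction.

    The fibre range [0.02, 0.06] maps linearly onto each metabolite's input
    concentration range.  Note the two *named* diets are fixed values that the
    affine map does not exactly reproduce; this map is used for scans only.
    """
    lo, hi = FIBRE_RANGE
    if not (lo <= f_pol <= hi):
        raise ValueError(f"fibre fraction {f_pol} outside scan domain [{lo}, {hi}]")
    plo, phi = PROTEIN_RANGE
    if not (plo <= f_prot <= phi):
        raise ValueError(f"protein fraction {f_prot} outside scan domain [{plo}, {phi}]")
    s = (f_pol - lo) / (hi - lo)
    conc = {j: a + s * (b - a) for j, (a, b) in _METABOLITE_RANGES.items()}
    return DietInput(
        f_pol_in=f_pol, f_prot_in=f_prot,
        c_mon_in=conc["mon"], c_la_in=conc["la"], c_ac_in=conc["ac"],
        c_pro_in=conc["pro"], c_but_in=conc["but"], v_in=v_in,
    )


def named_diet(name: str) -> DietInput:
    try:
        return {"reference": reference_diet, "hplf": hplf_diet}[name]()
    except KeyError:
        raise ValueError(f"unknown diet {name!r}; expected 'reference' or 'hplf'") from None
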