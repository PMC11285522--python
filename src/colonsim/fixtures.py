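"""Reduced model instances and randomized states for fast testing.

Each fixture is a well-posed (validating) configuration that runs in a few
seconds: a two-group lumen-only fermenter chain, a diffusion-only section,
a coarse 20-node crypt, and seeded random positive section states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ParameterSet, default_config
from .registry import BACT_SLICE, IV, N_D, N_V, SOLID_MASK
from .section import SectionState


@dataclass(frozen=True)
class FixtureSpec:
    kind: str           # "fermenter" | "diffusion" | "crypt" | "random_state"
    seed: int = 0


def two_group_fermenter() -> ParameterSet:
    """Lumen-centred fermenter: only the Bmon/Bla chain is active.

    All other uptakes are suppressed (minimal positive rates), secretion and
    absorption are off, so the lumen behaves as a fed fermentation vessel.
    """
    p = default_config()
    doc = p.model_dump(mode="python")
    tiny = 1e-12
    for name in ("la_ox_uptake", "h2_ac_uptake", "h2_me_uptake",
                 "prot_uptake", "h2s_h2_uptake", "muc_uptake"):
        doc["metabolism"][name]["q_max"] = tiny
    doc["metabolism"]["k_hyd_mucus"] = 0.0
    doc["secretion"]["mucus_per_goblet"] = 0.0
    doc["secretion"]["amp_per_cell"] = 0.0
    doc["absorption"]["metabolite_rate_L"] = 0.0
    doc["absorption"]["metabolite_rate_O"] = tiny
    doc["absorption"]["metabolite_rate_I"] = 2 * tiny
    doc["absorption"]["liquid_rate_L"] = 0.0
    doc["absorption"]["liquid_rate_O"] = tiny
    doc["absorption"]["liquid_rate_I"] = 2 * tiny
    doc["death"]["amp_coeff"] = 0.0
    doc["death"]["o2_coeff_phi"] = 0.0
    doc["death"]["o2_coeff_mu"] = 0.0
    return ParameterSet.model_validate(doc)


def diffusion_only() -> ParameterSet:
    """Section with every reaction and flow switched off except diffusion."""
    p = default_config()
    doc = p.model_dump(mode="python")
    tiny = 1e-12
    m = doc["metabolism"]
    for name in ("mon_uptake", "la_uptake", "la_ox_uptake", "h2_ac_uptake",
                 "h2_me_uptake", "prot_uptake", "h2s_h2_uptake", "muc_uptake"):
        m[name]["q_max"] = tiny
    m["k_hyd_pol"] = 0.0
    m["k_hyd_mucus"] = 0.0
    doc["death"]["basal"] = 0.0
    doc["death"]["amp_coeff"] = 0.0
    doc["death"]["o2_coeff_phi"] = 0.0
    doc["death"]["o2_coeff_mu"] = 0.0
    doc["h2s_toxicity"]["rate"] = 0.0
    doc["gas_transfer"]["k_la"] = {g: 0.0 for g in ("CH4", "CO2", "H2", "H2S")}
    doc["secretion"]["mucus_per_goblet"] = 0.0
    doc["secretion"]["amp_per_cell"] = 0.0
    doc["secretion"]["amp_decay"] = 0.0
    doc["absorption"]["metabolite_rate_L"] = 0.0
    doc["absorption"]["metabolite_rate_O"] = tiny
    doc["absorption"]["metabolite_rate_I"] = 2 * tiny
    doc["absorption"]["liquid_rate_L"] = 0.0
    doc["absorption"]["liquid_rate_O"] = tiny
    doc["absorption"]["liquid_rate_I"] = 2 * tiny
    doc["motility"]["attraction_velocity"] = 0.0
    return ParameterSet.model_validate(doc)


def small_crypt() -> ParameterSet:
    """Coarse 20-node crypt for sub-5-second relaxations."""
    p = default_config()
    doc = p.model_dump(mode="python")
    doc["crypt"]["n_nodes"] = 20
    doc["solver"]["crypt_t_max"] = 600.0
    doc["solver"]["crypt_t_chunk"] = 150.0
    doc["solver"]["crypt_stationarity_tol"] = 1e-5
    return ParameterSet.model_validate(doc)


def random_state(seed: int = 0, scale: float = 1.0) -> SectionState:
    """Seeded random positive section state respecting structural zeros.

    Bit-identical across calls with the same seed.
    """
    rng = np.random.default_rng(seed)
    f = np.zeros((3, N_V))
    raw = rng.uniform(0.0, 1.0, size=(3, N_V)) * SOLID_MASK
    raw[:, BACT_SLICE] *= 0.01
    raw[:, IV["pol"]] *= 0.05
    raw[:, IV["prot"]] *= 0.03
    raw[:, IV["l"]] = 0.0
    # rescale the solids to a random sub-unit total; liquid fills the rest
    target = rng.uniform(0.1, 0.6, size=3)
    raw *= (target / raw.sum(axis=1))[:, None]
    f[:] = raw
    f[:, IV["l"]] = 1.0 - f.sum(axis=1)
    c = rng.uniform(0.0, 50.0, size=(3, N_D)) * scale
    c[:, -2] = rng.uniform(0.0, 5.0, size=3)   # O2 in a physiological band
    c[:, -1] = rng.uniform(0.0, 0.5, size=3)   # AMPs
    st = SectionState(f, c, 0.0)
    st.validate()
    return st


def make_fixture(spec: FixtureSpec):
    """Dispatch on the fixture kind; see the individual builders."""
    if spec.kind == "fermenter":
        return two_group_fermenter()
    if spec.kind == "diffusion":
        return diffusion_only()
    if spec.kind == "crypt":
        return small_crypt()
    if spec.kind == "random_state":
        return random_state(spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
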