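"""Index sets of the colon-section model.

The model tracks two families of state variables in each of three
compartments (lumen ``L``, outer mucus ``O``, inner mucus ``I``):

* solid mixture components ``V`` — eight functional microbial groups plus
  mucus ``m``, polysaccharides ``pol``, dietary protein ``prot``, residual
  chyme ``r`` and liquid ``l`` — described by volume fractions that sum to
  one per compartment, and
* dissolved components ``D`` — monosaccharides, lactate, the three SCFAs,
  four gases, oxygen (kept as a solute, in arbitrary units) and
  antimicrobial peptides — described by concentrations (mM).

Each microbial group carries one inflammation-sensitivity class: ``phi``
(high), ``mu`` (moderate) or ``delta`` (low/null), expressed in the model
as an oxygen-dependent death-rate coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# --- microbial functional groups (set B), |B| = 8 ---------------------------
BACTERIA: tuple[str, ...] = (
    "Bmon_phi",   # monosaccharide degraders, high O2 sensitivity
    "Bmon_mu",    # monosaccharide degraders, moderate O2 sensitivity
    "Bla_phi",    # lactate fermenters, high O2 sensitivity
    "Bla_mu",     # lactate fermenters, moderate O2 sensitivity
    "Bla_delta",  # lactate consumers with oxidative pathway, O2 tolerant
    "BH2s_delta", # H2S producers (SRB + cysteine catabolizers), O2 tolerant
    "BH2a_phi",   # hydrogenotrophic acetogens
    "BH2m_phi",   # methanogenic archaea
)

SENSITIVITY: dict[str, str] = {
    "Bmon_phi": "phi",
    "Bmon_mu": "mu",
    "Bla_phi": "phi",
    "Bla_mu": "mu",
    "Bla_delta": "delta",
    "BH2s_delta": "delta",
    "BH2a_phi": "phi",
    "BH2m_phi": "phi",
}

# --- solid mixture components (set V), |V| = 13 ------------------------------
SOLIDS: tuple[str, ...] = BACTERIA + ("m", "pol", "prot", "r", "l")

# --- dissolved components (set D), |D| = 11 ----------------------------------
SOLUTES: tuple[str, ...] = (
    "mon", "la", "ac", "pro", "but",
    "CH4", "CO2", "H2", "H2S", "O2", "AMP",
)

# gases subject to liquid-to-gas transfer; O2 is deliberately excluded
# (it is treated as a solute throughout).
GASES: tuple[str, ...] = ("CH4", "CO2", "H2", "H2S")

COMPARTMENTS: tuple[str, ...] = ("L", "O", "I")
FLOW_FAMILIES: tuple[str, ...] = ("T", "S", "A", "D", "M")

SCFA: tuple[str, ...] = ("ac", "pro", "but")

IV: dict[str, int] = {name: k for k, name in enumerate(SOLIDS)}
ID: dict[str, int] = {name: k for k, name in enumerate(SOLUTES)}
IX: dict[str, int] = {name: k for k, name in enumerate(COMPARTMENTS)}
IB: dict[str, int] = {name: k for k, name in enumerate(BACTERIA)}

N_V = len(SOLIDS)
N_D = len(SOLUTES)
N_X = len(COMPARTMENTS)
N_B = len(BACTERIA)

BACT_SLICE = slice(0, N_B)


def solid_mask() -> np.ndarray:
    """Boolean (3, 13) mask of solid components structurally allowed per
    compartment.

    Polysaccharides, protein and residual chyme are bulky and cannot enter
    the mucus; microbial groups cannot enter the inner mucus.
    """
    mask = np.ones((N_X, N_V), dtype=bool)
    for comp in ("pol", "prot", "r"):
        mask[IX["O"], IV[comp]] = False
        mask[IX["I"], IV[comp]] = False
    for b in BACTERIA:
        mask[IX["I"], IV[b]] = False
    return mask


SOLID_MASK: np.ndarray = solid_mask()
SOLID_MASK.setflags(write=False)


@dataclass(frozen=True)
class SetsRegistry:
    """Frozen view of the model's index sets, for introspection/validation."""

    compartments: tuple[str, ...] = COMPARTMENTS
    solids: tuple[str, ...] = SOLIDS
    bacteria: tuple[str, ...] = BACTERIA
    solutes: tuple[str, ...] = SOLUTES
    gases: tuple[str, ...] = GASES
    flows: tuple[str, ...] = FLOW_FAMILIES
    sensitivity: dict[str, str] = field(default_factory=lambda: dict(SENSITIVITY))

    def __post_init__(self) -> None:
        if len(self.bacteria) != 8:
            raise ValueError("the model defines exactly 8 microbial groups")
        if len(self.solids) != 13 or len(self.solutes) != 11:
            raise ValueError("inconsistent component sets")
        if "O2" in self.gases:
            raise ValueError("O2 is a solute, never a transferable gas")
        missing = [b for b in self.bacteria if b not in self.sensitivity]
        if missing:
            raise ValueError(f"groups without a sensitivity class: {missing}")


REGISTRY = SetsRegistry()
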