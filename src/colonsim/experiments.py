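"""Numerical experiments: symbiosis biomarkers, diet-grid scans, breaches.

Four biomarkers indicate the health of the host-microbiota dialogue:

* luminal oxygen concentration (elevated O2 fosters dysbiosis),
* the share of the H2S-producing, inflammation-tolerant group in the lumen,
* PRR activation (drives AMP/mucus output, hence barrier quality),
* the differentiated-cell count per crypt (crypt maturity).

A fifth reported quantity, the mucus production rate, combines the goblet
count with PRR activation.  Breach scenarios perturb sections 2-4: scenario
A raises AMP production, C adds an oxygen bloom at the crypt base, and B
combines both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .config import (FIBRE_RANGE, PROTEIN_RANGE, DietInput, ParameterSet,
                     diet_from_fibre_protein)
from .pipeline import CouplingError, PipelineRun, run_pipeline
from .registry import BACT_SLICE, IB, ID, IX
from .section import mucus_production_rate

BIOMARKERS = ("luminal_o2", "bh2s_ratio", "prr_activation",
              "differentiated_cells", "mucus_production")


@dataclass(frozen=True)
class Scenario:
    """Epithelial-barrier breach applied to a window of sections.

    ``amp_multiplier`` scales the AMP production rate; ``o2_bloom`` is an
    additive oxygen influx at the crypt base (units/h).  Scenario A is pure
    AMP escalation, C the pure oxygen bloom, B their combination.
    """

    kind: Literal["A", "B", "C"]
    affected_sections: tuple[int, ...] = (2, 3, 4)
    amp_multiplier: float = 3.0
    o2_bloom: float = 0.26

    def __post_init__(self) -> None:
        if self.kind == "A" and self.o2_bloom_effective != 0.0:
            raise AssertionError("scenario A never has an oxygen bloom")

    @property
    def amp_multiplier_effective(self) -> float:
        return 1.0 if self.kind == "C" else self.amp_multiplier

    @property
    def o2_bloom_effective(self) -> float:
        return 0.0 if self.kind == "A" else self.o2_bloom


def scenario(kind: str, **kw) -> Scenario:
    return Scenario(kind=kind, **kw)  # type: ignore[arg-type]


def apply_scenario(sc: Scenario, section_index: int,
                   params: ParameterSet) -> ParameterSet:
    """Perturbed parameter set for one section (identity outside the window)."""
    if section_index not in sc.affected_sections:
        return params
    doc = params.model_dump(mode="python")
    doc["secretion"]["amp_per_cell"] *= sc.amp_multiplier_effective
    doc["crypt"]["o2_base_flux"] += sc.o2_bloom_effective
    return ParameterSet.model_validate(doc)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def biomarkers(run: PipelineRun) -> pd.DataFrame:
    """Per-section biomarker table (one row per section)."""
    rows = []
    for res in run.sections:
        st = res.state
        f_bact = float(st.f[IX["L"], BACT_SLICE].sum())
        f_h2s = float(st.f[IX["L"], IB["BH2s_delta"]])
        ratio = f_h2s / f_bact if f_bact > 0 else 0.0
        rows.append({
            "section": res.index,
            "luminal_o2": float(st.c[IX["L"], ID["O2"]]),
            "bh2s_ratio": ratio,
            "prr_activation": res.epithelium.prr_activation,
            "differentiated_cells": res.crypt_info.differentiated_cells,
            "proliferative_cells": res.crypt_info.proliferative_cells,
            "mucus_production": mucus_production_rate(res.epithelium, run.params),
            "v_out": res.flow.v_out,
            "f_B_lumen": f_bact,
            "f_B_outer": float(st.f[IX["O"], BACT_SLICE].sum()),
            "scfa_lumen": float(st.c[IX["L"], [ID["ac"], ID["pro"], ID["but"]]].sum()),
        })
    return pd.DataFrame(rows).set_index("section")


# ---------------------------------------------------------------------------
# diet grid scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DietGridSpec:
    fibre_range: tuple[float, float] = FIBRE_RANGE
    protein_range: tuple[float, float] = PROTEIN_RANGE
    shape: tuple[int, int] = (8, 8)

    def points(self) -> list[tuple[float, float]]:
        fib = np.linspace(*self.fibre_range, self.shape[0])
        pro = np.linspace(*self.protein_range, self.shape[1])
        return [(float(f), float(p)) for f in fib for p in pro]


def diet_scan(spec: DietGridSpec, params: ParameterSet,
              n_sections: int = 5, section: int | None = None) -> pd.DataFrame:
    """Run the full pipeline on every grid point; long-format section-5 table.

    Grid points are independent — results do not depend on evaluation order.
    Per-point failures are recorded (``error`` column) and the scan continues.
    """
    report_section = n_sections if section is None else section
    records = []
    for f_pol, f_prot in spec.points():
        diet = diet_from_fibre_protein(f_pol, f_prot)
        row = {"f_pol": f_pol, "f_prot": f_prot, "error": ""}
        try:
            run = run_pipeline(diet, params, n_sections=n_sections)
            table = biomarkers(run)
            for name in BIOMARKERS:
                row[name] = float(table.loc[report_section, name])
        except (CouplingError, RuntimeError) as exc:  # record and continue
            row["error"] = str(exc)
            for name in BIOMARKERS:
                row[name] = np.nan
        records.append(row)
    wide = pd.DataFrame(records)
    long = wide.melt(id_vars=["f_pol", "f_prot", "error"],
                     value_vars=list(BIOMARKERS),
                     var_name="biomarker", value_name="value")
    return long


# ---------------------------------------------------------------------------
# diet x scenario comparison
# ---------------------------------------------------------------------------

def compare_diets_under_scenario(sc: Scenario | None, params: ParameterSet,
                                 diets: dict[str, DietInput] | None = None,
                                 n_sections: int = 5) -> pd.DataFrame:
    """Reference vs HP/LF diets, with and without the breach scenario.

    Returns a long table: diet, condition (baseline/scenario), section,
    biomarker values and crypt counts, ready for Fig-13-style comparison.
    """
    from .config import hplf_diet, reference_diet

    diets = diets or {"reference": reference_diet(), "hplf": hplf_diet()}
    frames = []
    for diet_name, diet in diets.items():
        conditions: list[tuple[str, Scenario | None]] = [("baseline", None)]
        if sc is not None:
            conditions.append((f"scenario_{sc.kind}", sc))
        for cond_name, cond in conditions:
            run = run_pipeline(diet, params, scenario=cond, n_sections=n_sections)
            tab = biomarkers(run).reset_index()
            tab.insert(0, "diet", diet_name)
            tab.insert(1, "condition", cond_name)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)
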