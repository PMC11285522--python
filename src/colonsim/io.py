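"""Result serialization: tidy CSVs, a self-describing HDF5 archive, manifest.

Every ``write_run`` produces, inside the output directory:

* ``states.csv`` — long format (section, compartment, phase, component, value),
* ``biomarkers.csv`` — the per-section biomarker table,
* ``crypt_profiles.csv`` — long format (section, z, variable, value),
* ``run.h5`` — a structured archive with the full numeric state and the
  configuration snapshot embedded,
* ``manifest.json`` — config hash, schema version, solver diagnostics.

Identical runs produce byte-identical CSVs; the manifest hash changes iff
the configuration changes.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import ParameterSet
from .crypt import CELL_TYPES, CRYPT_SOLUTES
from .pipeline import PipelineRun
from .registry import COMPARTMENTS, SOLIDS, SOLUTES


def config_hash(params: ParameterSet) -> str:
    doc = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def states_frame(run: PipelineRun) -> pd.DataFrame:
    rows = []
    for res in run.sections:
        for xi, x in enumerate(COMPARTMENTS):
            for i, name in enumerate(SOLIDS):
                rows.append((res.index, x, "f", name, res.state.f[xi, i]))
            for j, name in enumerate(SOLUTES):
                rows.append((res.index, x, "c", name, res.state.c[xi, j]))
    return pd.DataFrame(rows, columns=["section", "compartment", "phase",
                                       "component", "value"])


def crypt_frame(run: PipelineRun) -> pd.DataFrame:
    rows = []
    for res in run.sections:
        z = res.crypt.grid.z
        for k, name in enumerate(CELL_TYPES):
            for zi, dens in zip(z, res.crypt.cells[k]):
                rows.append((res.index, zi, f"rho_{name}", dens))
        for zi, dens in zip(z, res.crypt.dcs):
            rows.append((res.index, zi, "rho_dcs", dens))
        for k, name in enumerate(CRYPT_SOLUTES):
            for zi, conc in zip(z, res.crypt.solutes[k]):
                rows.append((res.index, zi, f"c_{name}", conc))
    return pd.DataFrame(rows, columns=["section", "z", "variable", "value"])


def write_run(run: PipelineRun, out_dir: str | Path) -> Path:
    """Serialise a pipeline run; returns the manifest path.

    Overwrites idempotently, keeping one versioned backup of a previous
    manifest-bearing directory; partial writes are cleaned up on failure.
    """
    from .experiments import biomarkers  # deferred: experiments imports pipeline

    out = Path(out_dir)
    if (out / "manifest.json").exists():
        bak = out.with_name(out.name + ".bak")
        if bak.exists():
            shutil.rmtree(bak)
        shutil.copytree(out, bak)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        fmt = lambda df, p: df.to_csv(p, index=False, float_format="%.10g")
        fmt(states_frame(run), out / "states.csv")
        written.append(out / "states.csv")
        biomarkers(run).reset_index().to_csv(out / "biomarkers.csv", index=False,
                                             float_format="%.10g")
        written.append(out / "biomarkers.csv")
        fmt(crypt_frame(run), out / "crypt_profiles.csv")
        written.append(out / "crypt_profiles.csv")

        with h5py.File(out / "run.h5", "w") as h5:
            h5.attrs["config_json"] = json.dumps(run.params.model_dump(mode="json"))
            h5.attrs["config_hash"] = config_hash(run.params)
            h5.attrs["diet_json"] = json.dumps(run.diet.model_dump(mode="json"))
            for res in run.sections:
                grp = h5.create_group(f"section_{res.index}")
                grp.create_dataset("f", data=res.state.f)
                grp.create_dataset("c", data=res.state.c)
                grp.create_dataset("crypt_cells", data=res.crypt.cells)
                grp.create_dataset("crypt_solutes", data=res.crypt.solutes)
                grp.create_dataset("crypt_dcs", data=res.crypt.dcs)
                grp.attrs["v_in"] = res.flow.v_in
                grp.attrs["v_out"] = res.flow.v_out
                grp.attrs["coupling_iterations"] = res.coupling_iterations
                grp.attrs["coupling_residual"] = res.coupling_residual
        written.append(out / "run.h5")

        manifest = {
            "schema_version": run.params.schema_version,
            "config_hash": config_hash(run.params),
            "written_utc": datetime.now(timezone.utc).isoformat(),
            "n_sections": len(run.sections),
            "scenario": getattr(run.scenario, "kind", None),
            "sections": [
                {"index": r.index,
                 "stationary": bool(r.report.converged) if r.report else None,
                 "t_final": r.report.t_final if r.report else None,
                 "ode_residual": r.report.residual if r.report else None,
                 "coupling_iterations": r.coupling_iterations,
                 "coupling_residual": r.coupling_residual,
                 "v_out": r.flow.v_out}
                for r in run.sections
            ],
            "files": [p.name for p in written],
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return mpath
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def read_run_states(path: str | Path) -> dict[int, dict[str, np.ndarray]]:
    """Load the numeric states back from a run archive."""
    out: dict[int, dict[str, np.ndarray]] = {}
    with h5py.File(Path(path) / "run.h5", "r") as h5:
        for key in h5:
            idx = int(key.split("_")[1])
            grp = h5[key]
            out[idx] = {name: grp[name][...] for name in grp}
    return out
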