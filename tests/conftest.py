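"""Shared fixtures.

The coupled multi-section simulations are expensive (tens of seconds each),
so every test that needs a converged reference run, a diet grid or the
breach-scenario comparisons shares one session-scoped computation.
"""

from __future__ import annotations

import pandas as pd
import pytest

from colonsim.config import default_config, hplf_diet, reference_diet
from colonsim.experiments import (DietGridSpec, Scenario, biomarkers,
                                  diet_scan)
from colonsim.fixtures import diffusion_only, small_crypt, two_group_fermenter
from colonsim.metabolism import ProcessNetwork
from colonsim.pipeline import run_pipeline


@pytest.fixture(scope="session")
def params():
    return default_config()


@pytest.fixture(scope="session")
def network(params):
    return ProcessNetwork(params)


@pytest.fixture(scope="session")
def fermenter_params():
    return two_group_fermenter()


@pytest.fixture(scope="session")
def diffusion_params():
    return diffusion_only()


@pytest.fixture(scope="session")
def crypt_params():
    return small_crypt()


@pytest.fixture(scope="session")
def reference_run(params):
    """Five coupled sections under the reference diet."""
    return run_pipeline(reference_diet(), params)


@pytest.fixture(scope="session")
def diet_grid_3x3(params):
    """Coarse 3x3 fibre/protein scan, section-5 biomarkers (long format)."""
    return diet_scan(DietGridSpec(shape=(3, 3)), params)


@pytest.fixture(scope="session")
def scenario_tables(params):
    """Biomarker tables for {reference, hplf} x {baseline, A, B}."""
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for diet_name, diet in (("reference", reference_diet()), ("hplf", hplf_diet())):
        out[(diet_name, "baseline")] = biomarkers(run_pipeline(diet, params))
        for kind in ("A", "B"):
            run = run_pipeline(diet, params, scenario=Scenario(kind=kind))
            out[(diet_name, kind)] = biomarkers(run)
    return out
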