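"""Shared fixtures.

The transient simulations and the sixteen-case sweep are expensive, so they
run once per session at the default coarse resolution and are shared by the
module and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from wiop.calibration import run_sweep, table1_cases
from wiop.constitutive import MaterialParams
from wiop.model import EyeModel, default_materials


@pytest.fixture(scope="session")
def baseline_materials():
    return default_materials()


@pytest.fixture(scope="session")
def baseline_model():
    """Table 1 row 2 conditions: baseline cornea, IOP 15 mmHg, CCT 558 um."""
    return EyeModel(iop_mmhg=15.0)


@pytest.fixture(scope="session")
def pressurized(baseline_model):
    return baseline_model.pressurize()


@pytest.fixture(scope="session")
def puff_result(baseline_model):
    return baseline_model.simulate_air_puff()


@pytest.fixture(scope="session")
def mass_result(baseline_model):
    return baseline_model.simulate_falling_mass()


@pytest.fixture(scope="session")
def sweep_df():
    """The full sixteen-case sweep at coarse resolution."""
    df = run_sweep(table1_cases())
    assert (df.error.isin(["", "applanation not reached"])).all(), \
        df[["case_id", "error"]].to_string()
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(20240725)
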