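"""Shared fixtures: one synthetic trial bundle, reconstructed and fitted once."""

import pytest

from mucea.config import default_econ_inputs
from mucea.pipeline import ScenarioModel, fit_all, reconstruct_all
from mucea.synthetic_data import make_base_case_fixture


@pytest.fixture(scope="session")
def bundle():
    return make_base_case_fixture(seed=1)


@pytest.fixture(scope="session")
def reconstructed(bundle):
    ipd, fidelity = reconstruct_all(bundle.curves, bundle.risk_tables, total_n=350)
    return ipd, fidelity


@pytest.fixture(scope="session")
def fits(reconstructed):
    ipd, _ = reconstructed
    return fit_all(ipd)


@pytest.fixture(scope="session")
def us_overall_model(bundle, fits):
    return ScenarioModel(
        fits=fits,
        life_table=bundle.life_table,
        econ=default_econ_inputs("US", "overall"),
    )
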