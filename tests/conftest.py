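"""Shared fixtures: small synthetic fields and one cached contraction run."""

from __future__ import annotations

import pytest

from macnet import dynamics as dyn
from macnet import synthgen as sg


@pytest.fixture(scope="session")
def noiseless_params() -> sg.SynthParams:
    return sg.SynthParams(
        n_filaments=20, seed=7, poisson_noise=False, read_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noiseless_field(noiseless_params):
    truth, geom = sg.sample_filament_field(noiseless_params)
    img = sg.render_micrograph(geom, noiseless_params)
    return truth, geom, img


@pytest.fixture(scope="session")
def global_contraction_run():
    """One fully analyzed global-contraction series, shared across tests."""
    optics, cparams = sg.contraction_scenario("global", seed=0)
    truth, geom = sg.sample_filament_field(optics)
    actin, myosin, flows = sg.generate_contraction_series(geom, cparams, optics)
    reg = dyn.register_series(actin)
    lag1 = dyn.lag1_trace(reg.series)
    fields = dyn.piv(reg.series, lag_s=10.0)
    return {
        "optics": optics,
        "cparams": cparams,
        "actin": actin,
        "myosin": myosin,
        "flows": flows,
        "registered": reg,
        "lag1": lag1,
        "fields": fields,
    }
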