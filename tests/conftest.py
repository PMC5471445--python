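import dataclasses

import pytest

from qbump import ModelParams


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """Calibrated Drosophila defaults: N=30000, L~G(9,3), R~G(9,0.08), D=10."""
    return ModelParams()


@pytest.fixture(scope="session")
def small_population(default_params) -> ModelParams:
    """Same kinetics on a scaled-down microvillus population for MC tests."""
    return dataclasses.replace(default_params, n_microvilli=2000)
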