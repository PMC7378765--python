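import pytest

from vaxgame import GameParameters


@pytest.fixture(scope="session")
def baseline() -> GameParameters:
    return GameParameters.baseline()


@pytest.fixture(scope="session")
def center_params(baseline) -> GameParameters:
    """A calibration admitting an interior (center) equilibrium at
    (0.5, 8/13): stronger fine and discovery benefit, costlier active
    supervision."""
    return baseline.replace(CG1=1.9, RG=10.0, FV1=5.0)
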