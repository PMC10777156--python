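import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peatstab import (
    GeneratorConfig,
    MesocosmRecord,
    MixtureComposition,
    Phase,
    Treatment,
    generate_nee_series,
)
from peatstab.stability import phase_slope

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def noiseless_config():
    """Generator config with zero measurement noise."""
    return GeneratorConfig.default(noise_sd=0.0)


def single_cell_design(fraction: float, treatment: Treatment, n: int) -> list[MesocosmRecord]:
    """n replicate mesocosms of one composition x treatment cell."""
    comp = MixtureComposition.from_cuspidatum(fraction)
    return [MesocosmRecord(f"m{i}", comp, treatment, i + 1) for i in range(n)]


def fitted_drawdown_slopes(
    fraction: float,
    treatment: Treatment,
    n: int,
    seed: int,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Simulate n mesocosms of one cell and fit their drawdown-phase slopes."""
    kwargs = {"seed": seed}
    if noise_sd is not None:
        kwargs["noise_sd"] = noise_sd
    config = GeneratorConfig.default(**kwargs)
    series = generate_nee_series(single_cell_design(fraction, treatment, n), None, config)
    phase = Phase.DEEP_DRAWDOWN if treatment is Treatment.DEEP else Phase.MILD_DRAWDOWN
    return np.array([phase_slope(s, phase)[0] for s in series])


@pytest.fixture
def slope_sampler():
    return fitted_drawdown_slopes
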