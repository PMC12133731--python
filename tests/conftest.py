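import numpy as np
import pandas as pd
import pytest

from gtwrpanel import PanelDataset, SyntheticConfig, simulate_panel
from gtwrpanel.synthetic import COVARIATE_SCALES, SurfaceSpec


def make_config(**overrides) -> SyntheticConfig:
    """Small two-covariate config used across modules: a spatial-bump effect
    on pgdp, a temporal ramp on hp, constant intercept."""
    surfaces = {
        "intercept": SurfaceSpec(kind="constant", base_value=10.0),
        "pgdp": SurfaceSpec(
            kind="gaussian_bump", base_value=-1.0, amplitude=2.0,
            center=(600.0, 400.0), length_scale=200.0,
        ),
        "hp": SurfaceSpec(kind="linear_time", base_value=0.6, time_slope=-0.25),
    }
    cfg = dict(
        n_cities=40,
        years=tuple(range(2012, 2017)),
        layout="clustered",
        n_clusters=4,
        coefficient_surfaces=surfaces,
        covariate_scales={k: COVARIATE_SCALES[k] for k in ("pgdp", "hp")},
        noise_sd=0.5,
        missing_rate=0.0,
        seed=7,
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


@pytest.fixture(scope="session")
def small_panel() -> PanelDataset:
    """200 observations (40 cities x 5 years), known varying truth."""
    return simulate_panel(make_config())


@pytest.fixture(scope="session")
def flat_panel() -> PanelDataset:
    """Noiseless panel with constant coefficient surfaces everywhere."""
    surfaces = {
        "intercept": SurfaceSpec(kind="constant", base_value=8.0),
        "pgdp": SurfaceSpec(kind="constant", base_value=-1.2),
        "hp": SurfaceSpec(kind="constant", base_value=0.7),
    }
    return simulate_panel(make_config(coefficient_surfaces=surfaces, noise_sd=0.0, seed=3))


@pytest.fixture()
def grid25():
    """A 5 x 5 unit grid with a deterministic pseudo-random field."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    rng = np.random.default_rng(42)
    values = rng.normal(size=25) + 0.3 * coords[:, 0]
    return coords, values
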