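"""Shared test helpers: small phantom parameters and tiny network configs.

Everything is generated programmatically at test time; the small 16-voxel
phantom grid keeps unit tests fast while the default 32-voxel grid is used
where the test exercises the study-scale geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from triunet.networks import NetworkConfig
from triunet.phantom import PhantomParams


def small_phantom_params(noise_sd: float = 0.0) -> PhantomParams:
    """A 16-voxel phantom with the same structure as the default 32-voxel one."""
    return PhantomParams(
        grid_edge=16,
        brain_radii=(6.5, 7.0, 6.0),
        ventricle_base_fraction=0.03,
        ventricle_growth_per_year=0.02,
        region_base_radius=1.5,
        region_shrink_per_year=0.005,
        noise_sd=noise_sd,
    )


def tiny_network_config(**kw) -> NetworkConfig:
    """Smallest sensible Tri-UNet configuration (16-cube inputs)."""
    kw.setdefault("input_edge", 16)
    kw.setdefault("base_channels", 4)
    kw.setdefault("depth", 2)
    kw.setdefault("path_channels", 2)
    kw.setdefault("head_width", 8)
    kw.setdefault("norm_groups", 4)
    return NetworkConfig(**kw)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
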