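"""Shared fixtures: phantoms, optimized plans, and degradation cases.

The expensive objects (minimax-optimized plans and their reference doses)
are session-scoped and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctdr.phantoms import brain_spec, generate_phantom, thorax_spec
from ctdr.pipeline import SweepConfig, prepare_case


@pytest.fixture(scope="session")
def brain_config() -> SweepConfig:
    return SweepConfig(
        brain_spec(seed=42),
        setup_uncertainty_mm=3.0,
        density_uncertainty=0.035,
        beam_directions=("+x", "+y"),
        prescription=54.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def brain_case(brain_config):
    """Default brain-like phantom with a two-field minimax plan (3 mm / 3.5%)."""
    return prepare_case(brain_config)


@pytest.fixture(scope="session")
def thorax_config() -> SweepConfig:
    return SweepConfig(
        thorax_spec(seed=42),
        setup_uncertainty_mm=5.0,
        density_uncertainty=0.035,
        beam_directions=("-y", "+x"),
        prescription=54.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def thorax_case(thorax_config):
    """Chest-wall interface phantom with a two-field minimax plan (5 mm / 3.5%)."""
    return prepare_case(thorax_config)


@pytest.fixture()
def water_cube():
    """Noiseless homogeneous water volume with a spherical CTV."""
    from ctdr.phantoms import PhantomSpec, Primitive

    spec = PhantomSpec(
        "water",
        grid_shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        tissue_layout=[
            Primitive("sphere", 0.0, center=(47.0, 47.0, 47.0), radius=40.0)
        ],
        ctv=Primitive("sphere", 0.0, center=(47.0, 47.0, 47.0), radius=10.0),
        baseline_noise_sigma=0.0,
        seed=0,
    )
    return generate_phantom(spec)
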