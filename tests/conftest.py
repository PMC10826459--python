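import numpy as np
import pytest

from spheroflow.flow import FlowBC, PorousMedium, solve_flow
from spheroflow.geometry import build_geometry


@pytest.fixture(scope="session")
def slab():
    """Homogeneous 1 mm slab (inert inclusion) solved at 30 mbar."""
    geom = build_geometry(
        width=200, span=1000, spheroid_radius=30, spheroid_center=(100, 500),
        grid_spacing=5,
    )
    medium = PorousMedium(permeability=1.5e-16, permeability_spheroid=1.5e-16)
    bc = FlowBC.from_mbar(30.0, 0.0)
    field = solve_flow(geom, medium, bc)
    return geom, medium, bc, field


@pytest.fixture(scope="session")
def chip30():
    """Study geometry: 1 mm gel channel, 100 um spheroid at K_s = K/100, 30 mbar."""
    geom = build_geometry(width=1000, span=1000, spheroid_radius=100, grid_spacing=5)
    medium = PorousMedium(permeability=1.5e-16)
    bc = FlowBC.from_mbar(30.0, 0.0)
    field = solve_flow(geom, medium, bc)
    return geom, medium, bc, field


@pytest.fixture()
def zero_flow():
    """Factory: a no-flow field on a given geometry (diffusion-only runs)."""

    def make(geom):
        medium = PorousMedium(permeability=1e-16, permeability_spheroid=1e-16)
        field = solve_flow(geom, medium, FlowBC(1.0, 0.0))
        for arr in (field.flux_x, field.flux_y, field.velocity_x, field.velocity_y):
            arr[:] = 0.0
        return field

    return make


@pytest.fixture()
def uniform_flow():
    """Factory: uniform downstream plug flow of given speed (m/s)."""

    def make(geom, u):
        medium = PorousMedium(permeability=1e-16, permeability_spheroid=1e-16)
        field = solve_flow(geom, medium, FlowBC(1.0, 0.0))
        field.flux_x[:] = 0.0
        field.flux_y[:] = u
        field.velocity_x[:] = 0.0
        field.velocity_y[:] = u / 1e-6
        return field

    return make


@pytest.fixture(scope="session")
def small_synth():
    """A compact noisy synthetic stack with asymmetry, plus its ground truth."""
    from spheroflow.synth import SyntheticConfig, render_timelapse

    cfg = SyntheticConfig(asymmetry=1.25, motile=True, seed=7)
    stack, truth = render_timelapse(cfg)
    return cfg, stack, truth
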