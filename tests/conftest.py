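import numpy as np
import pytest

from cardiotet.cell_lr91 import CellConstants, StimulusProtocol
from cardiotet.mesh import build_adjacency, compute_diffusion_weights, generate_synthetic_mesh
from cardiotet.stepping import SimConfig


@pytest.fixture(scope="session")
def short_consts():
    """Short-plateau LR91 constants used for fast tissue runs."""
    return CellConstants.short_apd()


@pytest.fixture(scope="session")
def default_consts():
    return CellConstants()


@pytest.fixture(scope="session")
def tiny_mesh():
    """3x3x3 slab, 27 nodes."""
    return generate_synthetic_mesh(3, 3, 3, 0.25)


@pytest.fixture(scope="session")
def small_mesh():
    """6x6x6 slab, 216 nodes."""
    return generate_synthetic_mesh(6, 6, 6, 0.25)


@pytest.fixture(scope="session")
def tiny_adj(tiny_mesh):
    return build_adjacency(tiny_mesh)


@pytest.fixture(scope="session")
def tiny_weights(tiny_mesh, tiny_adj):
    return compute_diffusion_weights(tiny_mesh, tiny_adj, 0.1)


def corner_stimulus(mesh, spacing=0.25, duration=2.0, amplitude=-80.0, period=None):
    """Stimulus on the corner cube of a slab (helper shared across tests)."""
    r = 1.6 * spacing
    return StimulusProtocol.from_box(
        mesh, (0, r, 0, r, 0, r), amplitude=amplitude, duration=duration,
        period=period,
    )


@pytest.fixture(scope="session")
def tiny_stim(tiny_mesh):
    return corner_stimulus(tiny_mesh)


def quick_config(**kw):
    defaults = dict(
        scheme="coupled", integrator="euler", dt=0.005, t_total=1.0,
        output_stride=20, D=0.1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)
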