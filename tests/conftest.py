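import numpy as np
import pytest

from pcawarp.mesh import SurfaceMesh, unit_sphere_mesh
from pcawarp.synthetic import PopulationSpec, generate_population, make_template


@pytest.fixture(scope="session")
def sphere162() -> SurfaceMesh:
    return unit_sphere_mesh(162)


@pytest.fixture(scope="session")
def bumpy_star_mesh(sphere162) -> SurfaceMesh:
    """Star-shaped but clearly non-spherical surface around the origin."""
    u = sphere162.vertices
    r = 100.0 + 8.0 * np.sin(3.0 * u[:, 0]) + 5.0 * np.cos(2.0 * u[:, 2]) + 4.0 * u[:, 1]
    return sphere162.with_vertices(u * r[:, None])


@pytest.fixture(scope="session")
def small_population():
    """Cheap low-resolution population shared by shape-model and fit tests."""
    spec = PopulationSpec(
        n_heads=14, k_latent=3, v_count=162, vertex_noise_sd=0.2, seed=7
    )
    return generate_population(spec)


@pytest.fixture(scope="session")
def small_template(small_population):
    return make_template(small_population.spec)
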