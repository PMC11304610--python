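import pytest
from hypothesis import settings

from aortamimic import lattice as lat

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def slab():
    return lat.MatrixSlab()


@pytest.fixture(scope="session")
def design_cells():
    """Unit cells for all four published designs at default resolution."""
    out = {}
    for kind in lat.PUBLISHED_DESIGNS:
        spec, config = lat.published_design(kind)
        out[kind] = (spec, config, lat.build_unit_cell(spec))
    return out


@pytest.fixture(scope="session")
def design_lattices(slab):
    """Fully tessellated lattices for all four published designs.

    Built at the default tiling resolution (coarser than the single-cell
    fixture) to keep the instanced meshes light.
    """
    return {kind: lat.build_design(kind, slab) for kind in lat.PUBLISHED_DESIGNS}
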