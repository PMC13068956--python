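import pytest

from epimech import synthetic as syn


@pytest.fixture(scope="session")
def hertz_curve_694():
    """Noise-free Hertzian curve at the stiffened-tissue modulus."""
    return syn.gen_hertz_curve(E_eff_Pa=694.0, seed=0)


@pytest.fixture(scope="session")
def monolayer_field():
    """300-cell Voronoi field (0.1 mm² at 3000 cells/mm²) with truth."""
    return syn.gen_monolayer_images(seed=0)


@pytest.fixture(scope="session")
def pos_stack_30_20():
    """3D stack with 30 internalised and 20 bound particles."""
    return syn.gen_pos_stack(n_internalised=30, n_bound=20, seed=0)


@pytest.fixture(scope="session")
def extrusion_movie_2pct():
    """500-cell movie with a 2% extrusion fraction (10 events)."""
    return syn.gen_extrusion_movie(n_cells=500, extrusion_fraction=0.02,
                                   n_frames=60, seed=0)
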