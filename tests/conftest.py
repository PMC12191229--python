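import pytest

from imcpheno import SceneSpec, default_panel, make_cell_table, make_scene


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def default_scene(panel):
    """The default synthetic scene at a fixed seed, shared across tests."""
    spec = SceneSpec(seed=42)
    image, truth = make_scene(spec, panel)
    return spec, image, truth


@pytest.fixture(scope="session")
def six_sample_table(panel):
    """3 + 3 sample cell table with hidden phenotype labels."""
    spec = SceneSpec(n_cells=150, seed=5)
    cmap = {
        f"sample_{i + 1:02d}": ("control" if i < 3 else "treated")
        for i in range(6)
    }
    table, truth = make_cell_table(spec, panel, n_samples=6, condition_map=cmap)
    return table, truth
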