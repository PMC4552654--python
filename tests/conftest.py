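import numpy as np
import pytest

import forestprio as fp


def scaled_patch_specs(scale=1.0):
    """Patch classes with counts scaled for small test landscapes."""
    return (
        fp.PatchSpec("pa_analogue", max(1, int(3 * scale)), 13.54, 0.5),
        fp.PatchSpec("metso_analogue", max(1, int(2 * scale)), 5.36, 0.6),
        fp.PatchSpec("wkh_analogue", max(2, int(8 * scale)), 0.61, 0.8),
    )


@pytest.fixture(scope="session")
def small_config():
    return fp.LandscapeConfig(
        grid_height=48, grid_width=48, seed=7, patch_specs=scaled_patch_specs()
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    """48x48 synthetic landscape shared across tests (detailed, coarse, validation)."""
    return fp.generate_landscape(small_config)


def random_stack(rng, h=4, w=4, n_features=2, cell_size=60.0):
    """Random positive feature stack on a full mask."""
    data = rng.uniform(0.1, 10.0, size=(n_features, h, w))
    return fp.FeatureStack(
        names=[f"f{i}" for i in range(n_features)],
        data=data,
        weights=rng.uniform(0.5, 2.0, size=n_features),
        group_labels=[(f"f{i}", None) for i in range(n_features)],
        valid_mask=np.ones((h, w), dtype=bool),
        cell_size=cell_size,
    )
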