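import numpy as np
import pytest

from morphnet.synthetic_data import SyntheticSpec, generate_atlas, generate_subject
from morphnet.volume_io import AtlasParcellation, VolumeImage


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """6 regions in 3 generator groups, 200 voxels each."""
    return SyntheticSpec(
        shape=(12, 12, 12),
        n_regions=6,
        voxels_per_region=200,
        n_generator_groups=3,
        seed=0,
    )


@pytest.fixture
def small_atlas(small_spec) -> AtlasParcellation:
    return generate_atlas(small_spec)


@pytest.fixture
def small_volume(small_spec, small_atlas) -> VolumeImage:
    return generate_subject(small_spec, small_atlas, subject_index=0)


@pytest.fixture
def toy_volume() -> VolumeImage:
    rng = np.random.default_rng(42)
    return VolumeImage(values=rng.random((10, 10, 10)), voxel_size=(2.0, 2.0, 2.0))


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric binary adjacency with edge probability p."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return a + a.T
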