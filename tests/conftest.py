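import numpy as np
import pytest

from steatoquant import FieldSpec, generate_field, segment_fat


@pytest.fixture(scope="session")
def field_10pct():
    """A 512x512 artifact-free field at a 10% target fat fraction."""
    return generate_field(FieldSpec(target_fat_fraction=0.10, seed=11))


@pytest.fixture(scope="session")
def segmented_10pct(field_10pct):
    rgb, _truth = field_10pct
    return segment_fat(rgb)


@pytest.fixture(scope="session")
def ribbon_field():
    """A field with only elongated sinusoid ribbons, no vacuoles."""
    spec = FieldSpec(
        width_px=256,
        height_px=256,
        target_fat_fraction=0.0,
        artifact_density=3.0,
        artifact_kinds=("sinusoid",),
        seed=5,
    )
    return generate_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
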