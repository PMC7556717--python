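import numpy as np
import pytest

from ctcdte import (
    GateConfig,
    Image2D,
    MultichannelStack,
    SceneSpec,
    ctc_phenotype,
    debris_phenotype,
    leukocyte_phenotype,
    render_tile_scan,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """A random but valid 5-channel stack, 25 z-slices of 32x32."""
    pixels = rng.integers(0, 60000, size=(5, 25, 32, 32)).astype(np.uint16)
    return MultichannelStack(pixels=pixels)


@pytest.fixture
def uniform_image():
    """50x50 uniform image of intensity 100 (16-bit)."""
    return Image2D(np.full((50, 50), 100.0), bit_depth=16)


# Fixtures use absolute gate thresholds for exactness (background-derived
# thresholds are exercised separately).
@pytest.fixture
def abs_gates():
    return GateConfig(
        thresholds={"DAPI": 2000, "CK": 2000, "CD45": 2000, "TUB": 1000, "AR": 1000},
    )


@pytest.fixture(scope="session")
def benchmark_tile():
    """A 220-cell tile (40 CTC / 170 leukocyte / 10 debris) with ground truth."""
    spec = SceneSpec(
        cells=(
            (ctc_phenotype(), 40),
            (leukocyte_phenotype(), 170),
            (debris_phenotype(), 10),
        ),
        field_size_px=(768, 768),
        seed=7,
    )
    return render_tile_scan(spec)


@pytest.fixture(scope="session")
def small_tile():
    """A 55-cell tile (5 CTC / 50 leukocyte) with ground truth."""
    spec = SceneSpec(
        cells=((ctc_phenotype(), 5), (leukocyte_phenotype(), 50)),
        field_size_px=(512, 512),
        seed=11,
    )
    return render_tile_scan(spec)
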