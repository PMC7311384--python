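import numpy as np
import pytest

from segmix import synthgen


@pytest.fixture(scope="session")
def aggregate_field():
    """Default-condition aggregate field with its manifest (shared, read-only)."""
    cfg = synthgen.AggregateFieldConfig(seed=11)
    return synthgen.generate_aggregate_field(cfg)


@pytest.fixture(scope="session")
def tessellation():
    """100-cell mosaic with injected 5/6/7 rosettes and 10% mitoses."""
    cfg = synthgen.TessellationConfig(
        seed=5, rosette_injections=[5, 6, 7], mitotic_fraction=0.1
    )
    return synthgen.generate_tessellation(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
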