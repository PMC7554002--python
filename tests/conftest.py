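import numpy as np
import pandas as pd
import pytest

from risktree import (
    DssDefinition,
    ItemDictionary,
    ItemSpec,
    default_dss_definition,
)


@pytest.fixture
def small_dictionary() -> ItemDictionary:
    return ItemDictionary(
        [
            ItemSpec("attempt", "binary"),
            ItemSpec("ideation", "binary"),
            ItemSpec("mood", "ordinal", 5),
        ]
    )


@pytest.fixture
def dss_dictionary() -> ItemDictionary:
    specs = [ItemSpec(f"dss_{i:02d}", "ordinal", 5) for i in range(1, 10)]
    specs.append(ItemSpec("attempt", "binary"))
    return ItemDictionary(specs)


@pytest.fixture
def dss() -> DssDefinition:
    return default_dss_definition()


def random_node_frame(rng: np.random.Generator, n_records: int, n_items: int) -> pd.DataFrame:
    """A random node's records: ordinal items (codes 0..4) and a 0-4 outcome."""
    data = {
        f"it_{j}": rng.integers(0, 5, size=n_records) for j in range(n_items)
    }
    frame = pd.DataFrame(data)
    frame["danger"] = rng.integers(0, 5, size=n_records).astype(float)
    return frame
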