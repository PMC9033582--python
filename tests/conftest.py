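import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from mano import (
    BarcodeContext,
    BarcodeMap,
    collapse_clones,
    make_panel,
    panel_to_map,
    relative_growth_inhibition,
    scale_to_reference,
    simulate_screen,
)


@pytest.fixture(scope="session")
def ctx() -> BarcodeContext:
    return BarcodeContext()


@pytest.fixture(scope="session")
def small_map() -> BarcodeMap:
    entries = pd.DataFrame(
        {
            "barcode": ["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG", "ACGTACGTAC", "TTTTTTTTTT"],
            "variant_id": ["V1", "V1", "V1", "V2", "REF"],
            "clone_index": [1, 2, 3, 1, 1],
        }
    ).set_index("barcode")
    return BarcodeMap(entries, frozenset({"REF"}))


@pytest.fixture(scope="session")
def screen_sim():
    """A small but fully featured simulated screen shared across tests."""
    panel = make_panel(24, seed=11)
    return simulate_screen(panel, depth=200_000, seed=11)


@pytest.fixture(scope="session")
def screen_gi(screen_sim):
    counts = collapse_clones(screen_sim.counts, screen_sim.barcode_map)
    scaled = scale_to_reference(counts, "KRAS_G12V")
    return relative_growth_inhibition(scaled, screen_sim.counts.samples)


def embed(barcode: str, rng: np.random.Generator, read_length: int = 80) -> str:
    """Random read with the barcode cassette at a random offset."""
    cassette = "CTAGACTGCC" + barcode + "GGATCACTCT"
    pad = read_length - len(cassette)
    left = int(rng.integers(0, pad + 1))
    bases = "ACGT"
    bg = "".join(bases[i] for i in rng.integers(0, 4, pad))
    return bg[:left] + cassette + bg[left:]
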