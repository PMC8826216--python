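import numpy as np
import pandas as pd
import pytest

from colorprofiler import UCTable, rgb_to_hex
from colorprofiler.synthetic_fixtures import GradientSpec, PatchSpec, make_gradient_image, make_patch_image

CIEDE2000_FIXTURE = "src/colorprofiler/data/ciede2000_pairs.tsv"


@pytest.fixture(scope="session")
def ciede2000_pairs():
    """The 34 published CIEDE2000 verification Lab pairs with expected values."""
    from importlib.resources import files

    path = files("colorprofiler") / "data" / "ciede2000_pairs.tsv"
    df = pd.read_csv(str(path), sep="\t", comment="#")
    assert len(df) == 34
    return df


def random_uc_table(rng: np.random.Generator, n_colors: int, max_count: int = 500) -> UCTable:
    """A UC table of n distinct random colours with random counts."""
    codes = rng.choice(256**3, size=n_colors, replace=False)
    entries = {}
    for c in codes.tolist():
        entries[rgb_to_hex(((c >> 16) & 255, (c >> 8) & 255, c & 255))] = int(rng.integers(1, max_count))
    return UCTable(entries=entries, total_pixels=sum(entries.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def patch_fixture():
    spec = PatchSpec(
        patches=[((200, 40, 40), 500), ((40, 160, 60), 300), ((240, 220, 60), 150), ((90, 60, 160), 50)],
        width=40,
    )
    return make_patch_image(spec)


@pytest.fixture
def gradient_fixture():
    spec = GradientSpec(start=(200, 30, 30), end=(240, 230, 40), steps=48, pixels_per_step=4, band_height=6)
    return make_gradient_image(spec)
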