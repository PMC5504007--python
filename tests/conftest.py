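import numpy as np
import pytest

from gridstitch import synthetic


def source_for_grid(seed: int, rows: int, cols: int, tile: int,
                    overlap_pct: float, content: str = "texture",
                    margin: int = 40):
    """Source raster just large enough for the requested grid footprint."""
    w = int(tile * (1 + (cols - 1) * (1 - overlap_pct / 100.0))) + margin
    h = int(tile * (1 + (rows - 1) * (1 - overlap_pct / 100.0))) + margin
    return synthetic.generate_source(seed, w, h, content)


@pytest.fixture(scope="session")
def texture_512():
    """A 512x512 broadband texture shared by registration tests."""
    src, _ = synthetic.generate_source(11, 512, 512, "texture")
    return src


@pytest.fixture(scope="session")
def noiseless_acq():
    """3x3 grid, 64 px tiles, 20% overlap, perfectly regular stage."""
    src, _ = source_for_grid(5, 3, 3, 64, 20)
    return synthetic.simulate_acquisition(src, 3, 3, 64, 64, overlap_pct=20,
                                          alpha_deg=0, r_px=0, seed=5)


@pytest.fixture(scope="session")
def jittered_acq():
    """5x5 grid, 64 px tiles, 20% overlap, r=2 px jitter, 1 deg camera angle."""
    src, _ = source_for_grid(9, 5, 5, 64, 20)
    return synthetic.simulate_acquisition(src, 5, 5, 64, 64, overlap_pct=20,
                                          alpha_deg=1.0, r_px=2, seed=9)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
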