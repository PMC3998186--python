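from pathlib import Path

import numpy as np
import pytest

from chemotax.band_matrix import BandMatrix

REPO_ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = REPO_ROOT / "data" / "densitometry"


@pytest.fixture(scope="session")
def standards_path() -> Path:
    return DATA_DIR / "standards.csv"


@pytest.fixture(scope="session")
def tracks_path() -> Path:
    return DATA_DIR / "sample_tracks.csv"


@pytest.fixture
def small_matrix() -> BandMatrix:
    """3 samples x 2 primers (2 + 2 bands) with mixed polymorphism."""
    return BandMatrix(
        ("s1", "s2", "s3"),
        (("P1", 100), ("P1", 200), ("P2", 100), ("P2", 300)),
        np.array(
            [
                [1, 1, 0, 1],
                [1, 0, 1, 1],
                [1, 0, 0, 1],
            ],
            dtype=np.uint8,
        ),
    )


def random_band_matrix(rng: np.random.Generator, n_samples: int, n_bands: int) -> BandMatrix:
    presence = (rng.random((n_samples, n_bands)) < 0.5).astype(np.uint8)
    bands = tuple(("P1", 100 * (j + 1)) for j in range(n_bands))
    samples = tuple(f"s{i}" for i in range(n_samples))
    return BandMatrix(samples, bands, presence)
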