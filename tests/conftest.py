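import numpy as np
import pytest

from coastal_eae.config import PipelineConfig, RegionConfig
from coastal_eae.pipeline import run_pipeline
from coastal_eae.synth import generate_region


@pytest.fixture(scope="session")
def default_region():
    """The default synthetic study region (seed 42)."""
    return generate_region(RegionConfig())


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the default configuration."""
    return run_pipeline(PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def bfs_flood_fill(wet: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Independent 4-connected flood fill from the seed through wet pixels.

    Oracle implementation for connectivity checks: plain breadth-first
    search, no scipy.
    """
    nr, nc = wet.shape
    reached = np.zeros_like(wet, dtype=bool)
    frontier = [(r, c) for r, c in zip(*np.nonzero(wet & seed))]
    for rc in frontier:
        reached[rc] = True
    while frontier:
        r, c = frontier.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and wet[rr, cc] \
                    and not reached[rr, cc]:
                reached[rr, cc] = True
                frontier.append((rr, cc))
    return reached
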