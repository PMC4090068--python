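import numpy as np
import pandas as pd
import pytest

from bearcensus.capture import CaptureSummary
from bearcensus.scene import SimConfig, generate_scene

# the reconstructed satellite census counts: the integer triple consistent
# with 92 distinct individuals, an abundance estimate of 94, observer-B
# detection near 42% and a CI upper bound of 105 (synthetic fixture, not
# field data)
FIXTURE_COUNTS = (90, 40, 38)

# published distance-sampling selection table for the supported models:
# (delta-AICc, abundance estimate, SE)
SELECTION_TABLE = {
    "uniform/cosine": (0.00, 97.0, 17.8),
    "half-normal": (0.15, 104.0, 21.0),
    "half-normal/vis": (1.12, 105.0, 21.3),
    "half-normal/light": (1.38, 108.0, 22.1),
    "hazard-rate": (2.62, 100.0, 22.5),
}


@pytest.fixture(scope="session")
def fixture_summary() -> CaptureSummary:
    return CaptureSummary(*FIXTURE_COUNTS)


@pytest.fixture(scope="session")
def rowley_scene():
    """Default-condition island scene (94 bears, 1,100 km2)."""
    return generate_scene(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_imagery_scene():
    """Reduced-extent island for raster work: 94 bears + 200 rocks on 8 km2."""
    cfg = SimConfig(
        seed=5, island_area_km2=8.0, island_length_km=4.0,
        n_bears=94, n_rocks=200, n_ephemeral=0,
    )
    return generate_scene(cfg)


def simulate_truncated_half_normal(rng: np.random.Generator, n: int, sigma: float, w: float) -> np.ndarray:
    """Rejection-sample perpendicular distances with g(x)=exp(-x^2/2s^2) on [0,w]."""
    out: list[float] = []
    while len(out) < n:
        x = rng.uniform(0.0, w, 4 * n)
        keep = rng.random(4 * n) < np.exp(-(x**2) / (2 * sigma**2))
        out.extend(x[keep])
    return np.asarray(out[:n])


def distances_frame(x: np.ndarray, transect_id: str = "T01", stratum: str = "rowley") -> pd.DataFrame:
    n = len(x)
    return pd.DataFrame(
        {
            "transect_id": transect_id,
            "stratum": stratum,
            "perp_distance_m": x,
            "group_size": np.ones(n, int),
            "vis": "excellent",
            "light": "overcast",
        }
    )
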