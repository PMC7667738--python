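import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def naive_plate_cde(pixels, rows=16, cols=24, band_h=30, spacing=60, top_k=25):
    """Loop-based reimplementation of the whole CDE algorithm, kept free of
    the package's own code so it can serve as an independent oracle."""
    grid = np.asarray(pixels).tolist()
    out = {}
    for r in range(rows):
        band = grid[r * band_h : (r + 1) * band_h]
        profile = []
        for x in range(cols * spacing):
            column = sorted(row[x] for row in band)
            profile.append(sum(column[-top_k:]))
        for c in range(cols):
            win = profile[c * spacing : (c + 1) * spacing]
            top10 = sorted(win[20:40])[-10:]
            colony = (top10[4] + top10[5]) / 2
            background = (min(win[4:20]) + min(win[39:55])) / 2
            out[(r, c)] = colony - background
    return out


@pytest.fixture(scope="session")
def small_screen():
    """Noise-free 400-strain screen with planted mutants of every class."""
    from lightscreen.synthetic import SyntheticScreenSpec, simulate_screen_tables

    spec = SyntheticScreenSpec.with_counts(
        n_strains=400, n_sensitive=40, n_resistant=10, n_slow=10, noise_sd=0.0, seed=7
    )
    return spec, simulate_screen_tables(spec)


@pytest.fixture
def flat_window():
    return np.full(60, 100.0)
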