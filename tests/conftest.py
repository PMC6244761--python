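import numpy as np
import pytest

import monofilm as mf

# Documented settings for feature detection on noisy traces: a Savitzky-Golay
# window spanning ~1 mN/m of the pressure channel, and a profile grid fine
# enough to resolve the narrow modulus minimum of a flat plateau.
FEATURE_SMOOTHING = {"window_points": 21, "poly_order": 2}
FEATURE_GRID_STEP = 0.05


@pytest.fixture
def fractions():
    """Composition grid 0, 0.1, ..., 1.0."""
    return np.round(np.arange(0.0, 1.0001, 0.1), 10)


@pytest.fixture
def make_linear_isotherm():
    """Factory for a condensed-branch isotherm pi = intercept - slope * A."""

    def make(intercept=230.0, slope=5.0, area_hi=45.0, area_lo=35.0, n=201,
             noise=0.0, seed=0):
        areas = np.linspace(area_hi, area_lo, n)
        pressures = intercept - slope * areas
        if noise:
            pressures = pressures + np.random.default_rng(seed).normal(0.0, noise, n)
        return mf.Isotherm(areas, pressures)

    return make
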