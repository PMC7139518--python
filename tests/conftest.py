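"""Shared fixtures and hypothesis strategies."""

import numpy as np
import pytest
from hypothesis import strategies as st

from csfmarkov import TransitionRates, reference_rates


@pytest.fixture(scope="session")
def cd8_controls():
    return reference_rates("CD8", "controls")


@pytest.fixture(scope="session")
def cd4_controls():
    return reference_rates("CD4", "controls")


@pytest.fixture(scope="session")
def nk_controls():
    return reference_rates("NK", "controls")


def random_valid_rates(rng: np.random.Generator) -> TransitionRates:
    """Uniform draw from the feasible set (alpha1 + beta1 <= 1)."""
    a1 = rng.uniform(0, 1)
    b1 = rng.uniform(0, 1 - a1)
    return TransitionRates(
        alpha1=a1, alpha2=rng.uniform(0, 1), beta1=b1, beta2=rng.uniform(0, 1)
    )


@st.composite
def valid_rates(draw, min_rate=0.0, max_rate=1.0):
    """Hypothesis strategy for feasible TransitionRates.

    alpha1 and beta1 are scaled to keep alpha1 + beta1 <= 1.
    """
    floats = st.floats(min_rate, max_rate, allow_nan=False, allow_infinity=False)
    a1 = draw(floats)
    frac = draw(st.floats(0.0, 0.999))
    b1 = max(min_rate, frac * (1.0 - a1))
    a2 = draw(floats)
    b2 = draw(floats)
    return TransitionRates(alpha1=a1, alpha2=a2, beta1=b1, beta2=b2)


@st.composite
def interior_rates(draw):
    """Rates strictly inside (0, 1) with alpha1 + beta1 bounded away from 1."""
    floats = st.floats(1e-3, 0.9, allow_nan=False)
    a1 = draw(floats)
    b1 = draw(st.floats(1e-3, 0.9)) * (1.0 - a1)
    b1 = max(b1, 1e-4)
    return TransitionRates(
        alpha1=a1, alpha2=draw(floats), beta1=b1, beta2=draw(floats)
    )
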