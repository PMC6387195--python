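"""Shared oracles and helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def chi2_sf_oracle(x: float) -> float:
    """Upper tail of the chi-square(df=1) by direct numerical integration.

    Independent of scipy.stats' special-function implementation: integrates
    the density exp(-t/2) / sqrt(2 pi t) with adaptive quadrature.
    """
    from scipy.integrate import quad

    if x <= 0:
        return 1.0

    def pdf(t: float) -> float:
        return math.exp(-t / 2.0) / math.sqrt(2.0 * math.pi * t)

    val, _ = quad(pdf, x, np.inf, epsabs=0.0, epsrel=1e-12, limit=200)
    return val


def match_spots(detected, truth, radius: float = 2.0) -> int:
    """Greedy one-to-one matching of detections to truth within a radius."""
    used: set[int] = set()
    tp = 0
    for s in detected:
        best, best_d = None, radius
        for i, t in enumerate(truth):
            if i in used or t.channel != s.channel:
                continue
            d = math.hypot(s.x - t.x, s.y - t.y)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            tp += 1
    return tp


@pytest.fixture
def rendered_scene():
    """50 simulated cells rendered noise-free, with truth, reused per test."""
    from deltascope import ImageSpec, get_preset, grid_layout, render_image, simulate_counts

    params = get_preset("BRCA1_carrier", seed=11)
    _, counts = simulate_counts(params, 50, sample="sim")
    side = 8 * 44 + 8
    spec = ImageSpec(
        width=side, height=side, cell_layout=grid_layout(50, side, side)
    )
    stack, truth = render_image(counts, spec, seed=3)
    return counts, spec, stack, truth
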