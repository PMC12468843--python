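"""Fixture generators emulating the example classes analysed with the method.

Two are exact parametric families (binomial pmf, exponential density); two
are seeded synthetic histograms standing in for figure-only applied data:
a unimodal disease-incidence histogram over 5-year age bands and a strictly
increasing stress-load profile along a beam.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np

from .continuous import DensityModel
from .discrete import DiscreteDistribution, make_distribution
from .errors import DomainError


def fixture_binomial(n: int, p: float) -> DiscreteDistribution:
    """Exact Binomial(n, p) pmf via the multiplicative recurrence
    p_{k+1} = p_k * (n-k)/(k+1) * p/(1-p)."""
    if n < 1 or int(n) != n:
        raise DomainError(f"n must be a positive integer, got {n}")
    if not (0.0 < p < 1.0):
        raise DomainError(f"p must be in (0, 1), got {p}")
    probs = np.empty(n + 1)
    probs[0] = (1.0 - p) ** n
    ratio = p / (1.0 - p)
    for k in range(n):
        probs[k + 1] = probs[k] * (n - k) / (k + 1) * ratio
    return make_distribution(list(range(n + 1)), probs, renormalize=True)


def fixture_exponential(rate: float) -> DensityModel:
    """Exponential density rate*e^{-rate*x} on (0, inf) with closed-form
    masses and entropy integrals."""
    return DensityModel.exponential(rate)


def _age_band_labels(bins: int) -> list[str]:
    return [f"{5 * i}-{5 * i + 4}" for i in range(bins)]


def fixture_incidence(bins: int = 20, peak_bin: int = 4, decay: float = 0.8,
                      seed: int = 0) -> DiscreteDistribution:
    """Unimodal incidence histogram over ``bins`` 5-year age bands.

    Probabilities rise strictly to ``peak_bin`` and fall strictly after it,
    with multiplicative steps jittered around ``decay`` (so there are no
    ties and every Hahn split is binary).  With the defaults the peak mass
    comes out near 12%, emulating a disease most prevalent in the 20-24
    band and tapering on both sides.
    """
    if bins < 3:
        raise DomainError(f"need at least 3 bins, got {bins}")
    if not (0 <= peak_bin < bins):
        raise DomainError(f"peak_bin {peak_bin} outside 0..{bins - 1}")
    if not (0.0 < decay < 1.0):
        raise DomainError(f"decay must be in (0, 1), got {decay}")
    rng = np.random.default_rng(seed)
    w = np.empty(bins)
    w[peak_bin] = 1.0
    for i in range(peak_bin - 1, -1, -1):  # falling toward younger ages
        w[i] = w[i + 1] * decay * rng.uniform(0.85, 1.15)
    for i in range(peak_bin + 1, bins):    # falling toward older ages
        w[i] = w[i - 1] * decay * rng.uniform(0.85, 1.15)
    return make_distribution(_age_band_labels(bins), w, renormalize=True)


def fixture_monotone_load(bins: int = 21, seed: int = 0) -> DiscreteDistribution:
    """Strictly increasing load profile over ``bins`` positions, emulating a
    beam whose stress share rises monotonically toward one end (about 10%
    at the loaded end for the default 21 positions)."""
    if bins < 2:
        raise DomainError(f"need at least 2 bins, got {bins}")
    rng = np.random.default_rng(seed)
    # strictly positive jittered increments guarantee strict monotonicity
    increments = rng.uniform(0.5, 1.5, size=bins)
    w = np.cumsum(increments)
    return make_distribution([f"pos_{i}" for i in range(bins)], w,
                             renormalize=True)
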