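"""Part summaries: mass, conditional entropy, diversity, degree of uniformity.

The degree of uniformity of a part P is D_P / c_P, where c_P is the part's
probability mass and D_P = exp(H_P) is the exponential of the conditional
Shannon entropy of the part (the Hill number of order one of the renormalized
restriction).  Its reciprocal c_P / D_P is the degree of inequality or
concentration.  All entropies are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PartSummary:
    """Summary statistics of a part of a distribution.

    Attributes
    ----------
    mass : float
        Probability mass c_P of the part, in (0, 1].
    entropy : float
        Conditional Shannon entropy H_P of the renormalized part, in nats.
        Non-negative for discrete parts; may be negative (differential
        entropy) for continuous parts.
    diversity : float
        D_P = exp(H_P); the support length of the uniform distribution with
        the same entropy as the part.
    dou : float
        Degree of uniformity D_P / c_P; always positive.
    """

    mass: float
    entropy: float
    diversity: float
    dou: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mass <= 1.0 + 1e-12):
            raise ValueError(f"mass must be in (0, 1], got {self.mass}")
        if not math.isfinite(self.entropy):
            raise ValueError("entropy must be finite")

    @classmethod
    def from_mass_entropy(cls, mass: float, entropy: float) -> "PartSummary":
        diversity = math.exp(entropy)
        return cls(mass=mass, entropy=entropy, diversity=diversity,
                   dou=diversity / mass)

    @property
    def threshold(self) -> float:
        """Hahn threshold c_P / D_P = 1 / dou for splitting this part."""
        return self.mass / self.diversity
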