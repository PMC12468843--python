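"""Constructing distributions with a designed non-trivial null set.

A null set Z of the degree-of-uniformity measure is a part whose every
subset is exactly as uniformly distributed as the whole distribution.  The
construction fixes a whole-distribution diversity D, a null-set mass c_Z,
and uniformity factors eta1 > 1 (for P, with dou = D*eta1) and eta2 in
(0, 1) (for N, with dou = D*eta2).  The weighted-geometric-mean conservation
law forces

    eta1^{c_P} * eta2^{c_N} = 1   and   c_P + c_N = 1 - c_Z,

whose unique solution is

    c_P = -ln(eta2) (1 - c_Z) / (ln eta1 - ln eta2),
    c_N =  ln(eta1) (1 - c_Z) / (ln eta1 - ln eta2).

(The numerators must be assigned this way round: cross-multiplying makes
c_P ln eta1 + c_N ln eta2 vanish identically.  Swapping them only satisfies
the constraint in the symmetric case eta1*eta2 = 1.)  Realizations place
mass at three uniform heights 1/(D eta1), 1/D, 1/(D eta2); the discrete one
needs the implied atom counts to be integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .continuous import DensityModel
from .discrete import DiscreteDistribution, make_distribution
from .errors import DomainError, InfeasibleDesignError

_INT_TOL = 1e-9


def solve_masses(cZ: float, eta1: float, eta2: float) -> tuple[float, float]:
    """Solve {c_P ln eta1 + c_N ln eta2 = 0, c_P + c_N = 1 - c_Z} for the
    masses of the positive and negative parts."""
    if not (0.0 <= cZ < 1.0):
        raise DomainError(f"cZ must be in [0, 1), got {cZ}")
    if not (eta1 > 1.0):
        raise DomainError(f"eta1 must be > 1, got {eta1}")
    if not (0.0 < eta2 < 1.0):
        raise DomainError(f"eta2 must be in (0, 1), got {eta2}")
    l1, l2 = math.log(eta1), math.log(eta2)
    rest = 1.0 - cZ
    cP = -l2 * rest / (l1 - l2)
    cN = l1 * rest / (l1 - l2)
    assert abs(cP * l1 + cN * l2) <= 1e-10 * max(1.0, abs(l1), abs(l2))
    return cP, cN


@dataclass(frozen=True)
class NullDesign:
    """A solved design: target diversity D, masses, and uniformity factors.

    dou of the three parts of any realization will be (D*eta1, D, D*eta2).
    """

    D: float
    cZ: float
    eta1: float
    eta2: float
    cP: float
    cN: float

    @classmethod
    def create(cls, D: float, cZ: float, eta1: float,
               eta2: float) -> "NullDesign":
        if not (D > 0):
            raise DomainError(f"D must be > 0, got {D}")
        cP, cN = solve_masses(cZ, eta1, eta2)
        return cls(D=float(D), cZ=float(cZ), eta1=float(eta1),
                   eta2=float(eta2), cP=cP, cN=cN)

    @property
    def atom_counts(self) -> tuple[float, float, float]:
        """Implied (n_P, n_Z, n_N) atom counts of a discrete realization:
        n_P = c_P D eta1, n_Z = c_Z D, n_N = c_N D eta2 (not necessarily
        integers)."""
        return (self.cP * self.D * self.eta1,
                self.cZ * self.D,
                self.cN * self.D * self.eta2)


def realize_discrete(design: NullDesign) -> DiscreteDistribution:
    """Realize the design as a discrete distribution: n_P atoms of
    probability 1/(D eta1), n_Z atoms of 1/D, n_N atoms of 1/(D eta2),
    labeled 1..K in P, Z, N order."""
    counts = dict(zip(("n_P", "n_Z", "n_N"), design.atom_counts))
    bad = {name: x for name, x in counts.items()
           if abs(x - round(x)) > _INT_TOL or round(x) < 0}
    if bad:
        detail = ", ".join(f"{name} = {x!r}" for name, x in bad.items())
        raise InfeasibleDesignError(
            f"design requires non-integer atom counts ({detail}); "
            "adjust D, cZ, eta1 or eta2")
    nP, nZ, nN = (int(round(counts[k])) for k in ("n_P", "n_Z", "n_N"))
    probs = ([1.0 / (design.D * design.eta1)] * nP
             + [1.0 / design.D] * nZ
             + [1.0 / (design.D * design.eta2)] * nN)
    labels = list(range(1, nP + nZ + nN + 1))
    # heights are exact by construction; renormalize only mops up float dust
    return make_distribution(labels, probs, renormalize=True)


def realize_continuous(design: NullDesign) -> DensityModel:
    """Realize the design as a piecewise-constant density with consecutive
    segments of lengths (c_P D eta1, c_Z D, c_N D eta2) at heights
    (1/(D eta1), 1/D, 1/(D eta2)), starting at 0."""
    lengths = design.atom_counts  # same products, no integrality needed
    heights = (1.0 / (design.D * design.eta1),
               1.0 / design.D,
               1.0 / (design.D * design.eta2))
    breaks = [0.0]
    hs = []
    for length, h in zip(lengths, heights):
        if length > 0:
            breaks.append(breaks[-1] + length)
            hs.append(h)
    return DensityModel.piecewise_constant(breaks, hs)
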