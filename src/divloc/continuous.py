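"""Continuous densities over interval unions: mass, differential entropy,
degree of uniformity, and density level sets.

Parts of a continuous distribution are finite unions of disjoint open
intervals (the recursive splitter only ever produces these for piecewise-
monotone densities).  Endpoint open/closed status is not tracked: boundary
points have Lebesgue measure zero and do not affect any summary.

For a region P with mass c = int_P p, the conditional differential entropy is
H = -int_P (p/c) ln(p/c) = ln c - (1/c) int_P p ln p, the diversity is
D = exp(H) (which may be below 1), and the degree of uniformity D/c is
always positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import DomainError, NumericalError, ValidationError
from .summary import PartSummary

INF = math.inf

# kinds of declared density segments
INCREASING = "increasing"
DECREASING = "decreasing"
CONSTANT = "constant"

DEFAULT_AT_TOL = 1e-9      # relative tolerance for matching a constant level
DEFAULT_ROOT_TOL = 1e-10   # |dx| tolerance for level-crossing roots
DEFAULT_TAIL_MASS = 1e-12  # mass below which an infinite tail is truncated


class IntervalUnion:
    """Finite union of disjoint open intervals, kept sorted and merged."""

    __slots__ = ("intervals",)

    def __init__(self, intervals: Iterable[tuple[float, float]] = ()) -> None:
        ivs = []
        for lo, hi in intervals:
            lo, hi = float(lo), float(hi)
            if lo < hi:
                ivs.append((lo, hi))
        ivs.sort()
        merged: list[tuple[float, float]] = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        self.intervals: tuple[tuple[float, float], ...] = tuple(merged)

    @classmethod
    def empty(cls) -> "IntervalUnion":
        return cls(())

    @classmethod
    def single(cls, lo: float, hi: float) -> "IntervalUnion":
        return cls(((lo, hi),))

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    @property
    def total_length(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)

    def intersect(self, lo: float, hi: float) -> "IntervalUnion":
        return IntervalUnion((max(a, lo), min(b, hi))
                             for a, b in self.intervals)

    def union(self, other: "IntervalUnion") -> "IntervalUnion":
        return IntervalUnion(self.intervals + other.intervals)

    def contains(self, x: float) -> bool:
        return any(lo < x < hi for lo, hi in self.intervals)

    def within(self, lo: float, hi: float, tol: float = 1e-12) -> bool:
        return all(a >= lo - tol and b <= hi + tol for a, b in self.intervals)

    def shift(self, dx: float) -> "IntervalUnion":
        return IntervalUnion((a + dx, b + dx) for a, b in self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalUnion) and self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(self.intervals)

    def __repr__(self) -> str:
        return f"IntervalUnion({list(self.intervals)!r})"

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class DensityModel:
    """A univariate probability density with declared monotone structure.

    ``segments`` partitions the support into pieces each declared
    monotone-increasing, monotone-decreasing, or constant; the level-set
    splitter relies on these declarations to bracket crossings.  Built-in
    families (exponential, piecewise-constant/uniform) carry closed forms
    for masses and entropy integrals; anything else falls back to adaptive
    quadrature.
    """

    support: tuple[float, float]
    pdf: Callable[[np.ndarray], np.ndarray]
    segments: tuple[tuple[float, float, str], ...]
    family: str = "custom"
    params: tuple = ()

    # ---------------------------------------------------------------- build
    @classmethod
    def exponential(cls, rate: float) -> "DensityModel":
        """Density rate*exp(-rate*x) on (0, inf), monotone decreasing."""
        if not (rate > 0):
            raise DomainError(f"rate must be > 0, got {rate}")

        def pdf(x, _r=float(rate)):
            x = np.asarray(x, dtype=float)
            return np.where(x >= 0, _r * np.exp(-_r * x), 0.0)

        return cls(support=(0.0, INF), pdf=pdf,
                   segments=((0.0, INF, DECREASING),),
                   family="exponential", params=(float(rate),))

    @classmethod
    def piecewise_constant(cls, breaks: Sequence[float],
                           heights: Sequence[float],
                           tol: float = 1e-9) -> "DensityModel":
        """Step density: heights[i] on (breaks[i], breaks[i+1])."""
        br = tuple(float(b) for b in breaks)
        hs = tuple(float(h) for h in heights)
        if len(br) != len(hs) + 1:
            raise ValidationError("need len(breaks) == len(heights) + 1")
        if any(b2 <= b1 for b1, b2 in zip(br, br[1:])):
            raise ValidationError("breaks must be strictly increasing")
        if any(h < 0 for h in hs):
            raise ValidationError("heights must be non-negative")
        total = sum(h * (b2 - b1) for h, b1, b2 in zip(hs, br, br[1:]))
        if abs(total - 1.0) > tol:
            raise ValidationError(
                f"piecewise density integrates to {total!r}, not 1")

        def pdf(x, _br=np.asarray(br), _hs=np.asarray(hs)):
            x = np.asarray(x, dtype=float)
            idx = np.clip(np.searchsorted(_br, x, side="right") - 1,
                          0, len(_hs) - 1)
            out = _hs[idx]
            return np.where((x >= _br[0]) & (x <= _br[-1]), out, 0.0)

        segs = tuple((b1, b2, CONSTANT) for b1, b2 in zip(br, br[1:]))
        return cls(support=(br[0], br[-1]), pdf=pdf, segments=segs,
                   family="piecewise_constant", params=(br, hs))

    @classmethod
    def uniform(cls, a: float, b: float) -> "DensityModel":
        if not (b > a):
            raise DomainError("need b > a")
        h = 1.0 / (b - a)
        return cls.piecewise_constant((a, b), (h,))

    @classmethod
    def from_callable(cls, pdf: Callable, support: tuple[float, float],
                      segments: Sequence[tuple[float, float, str]],
                      check_points: int = 64) -> "DensityModel":
        """Wrap an arbitrary density; monotonicity declarations are
        spot-checked on ``check_points`` sampled points per finite segment."""
        segs = tuple((float(a), float(b), k) for a, b, k in segments)
        model = cls(support=(float(support[0]), float(support[1])),
                    pdf=pdf, segments=segs, family="custom")
        model._spot_check(check_points)
        return model

    def _spot_check(self, n: int) -> None:
        for lo, hi, kind in self.segments:
            a = lo if math.isfinite(lo) else (hi - 64 if math.isfinite(hi) else -64)
            b = hi if math.isfinite(hi) else a + 64
            xs = np.linspace(a + (b - a) * 1e-6, b - (b - a) * 1e-6, n)
            vals = np.asarray(self.pdf(xs), dtype=float)
            if np.any(vals < -1e-12):
                raise ValidationError(f"density negative on segment ({lo},{hi})")
            d = np.diff(vals)
            if kind == INCREASING and np.any(d < -1e-9):
                raise ValidationError(f"segment ({lo},{hi}) declared increasing "
                                      "but decreases at sampled points")
            if kind == DECREASING and np.any(d > 1e-9):
                raise ValidationError(f"segment ({lo},{hi}) declared decreasing "
                                      "but increases at sampled points")
            if kind == CONSTANT and np.ptp(vals) > 1e-9 * max(vals.max(), 1.0):
                raise ValidationError(f"segment ({lo},{hi}) declared constant "
                                      "but varies at sampled points")

    @property
    def whole(self) -> IntervalUnion:
        return IntervalUnion.single(*self.support)

    # ------------------------------------------------- elementary integrals
    def _mass_interval(self, a: float, b: float) -> float:
        """int_a^b p(x) dx, closed form when the family provides one."""
        if a >= b:
            return 0.0
        if self.family == "exponential":
            r = self.params[0]
            upper = 0.0 if b == INF else math.exp(-r * b)
            return math.exp(-r * a) - upper
        if self.family == "piecewise_constant":
            br, hs = self.params
            total = 0.0
            for h, b1, b2 in zip(hs, br, br[1:]):
                total += h * max(0.0, min(b, b2) - max(a, b1))
            return total
        return self._quad(lambda x: self.pdf(x), a, b)

    def _plogp_interval(self, a: float, b: float) -> float:
        """int_a^b p(x) ln p(x) dx (0*ln 0 := 0)."""
        if a >= b:
            return 0.0
        if self.family == "exponential":
            r = self.params[0]
            # int p ln p = ln(r) * mass - r * int x p dx, with
            # int_a^b x r e^{-rx} dx = (a + 1/r) e^{-ra} - (b + 1/r) e^{-rb}
            mass = self._mass_interval(a, b)
            tail_b = 0.0 if b == INF else (b + 1.0 / r) * math.exp(-r * b)
            xmean = (a + 1.0 / r) * math.exp(-r * a) - tail_b
            return math.log(r) * mass - r * xmean
        if self.family == "piecewise_constant":
            br, hs = self.params
            total = 0.0
            for h, b1, b2 in zip(hs, br, br[1:]):
                w = max(0.0, min(b, b2) - max(a, b1))
                if w > 0 and h > 0:
                    total += h * math.log(h) * w
            return total

        def f(x):
            p = np.asarray(self.pdf(x), dtype=float)
            return np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)

        return self._quad(f, a, b)

    @staticmethod
    def _quad(f, a: float, b: float) -> float:
        val, err = integrate.quad(f, a, b, limit=200)
        if not math.isfinite(val):
            raise NumericalError(f"quadrature diverged on ({a},{b})")
        return val

    def finite_tail_bound(self, lo: float,
                          tail_mass: float = DEFAULT_TAIL_MASS) -> float:
        """Point B > lo such that the mass of (B, inf) is below ``tail_mass``;
        used to truncate infinite tails for sampling and bracketing."""
        b = max(lo + 1.0, 1.0)
        for _ in range(200):
            if self._mass_interval(b, INF) < tail_mass:
                return b
            b *= 2.0
        raise NumericalError("could not bound infinite tail")


def mass_on(density: DensityModel, region: IntervalUnion) -> float:
    """Probability mass of a region (sum of closed-form or quadrature
    integrals over its component intervals)."""
    lo, hi = density.support
    if not region.within(lo, hi):
        raise DomainError(f"region {region!r} outside support ({lo},{hi})")
    return sum(density._mass_interval(a, b) for a, b in region)


def summarize_region(density: DensityModel,
                     region: IntervalUnion) -> PartSummary:
    """Mass, conditional differential entropy, diversity, and degree of
    uniformity of a region.  Diversity may be below one (differential
    entropy may be negative); the degree of uniformity is always positive."""
    c = mass_on(density, region)
    if c <= 0.0:
        raise DomainError("region has zero mass")
    j = sum(density._plogp_interval(a, b) for a, b in region)
    entropy = math.log(c) - j / c
    return PartSummary.from_mass_entropy(c, entropy)


def _crossing(density: DensityModel, t: float, a: float, b: float,
              kind: str, root_tol: float, grid: int) -> float | None:
    """Unique x in (a, b) with p(x) = t on a declared monotone piece, or
    None when the piece lies entirely on one side of the level."""
    if density.family == "exponential":
        r = density.params[0]
        x = -math.log(t / r) / r
        return x if a < x < b else None
    b_eff = b if math.isfinite(b) else density.finite_tail_bound(a)
    a_eff = a  # supports here are bounded below or exponential-style tails
    fa = float(density.pdf(np.asarray([a_eff + root_tol]))[0]) - t
    fb = float(density.pdf(np.asarray([b_eff - root_tol]))[0]) - t
    if fa == 0.0:
        return a_eff
    if fb == 0.0:
        return b_eff
    if fa * fb > 0:
        return None
    # scan for the sign-change bracket, then bisect
    xs = np.linspace(a_eff, b_eff, grid)
    vals = np.asarray(density.pdf(xs), dtype=float) - t
    sign = np.sign(vals)
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if idx.size == 0:
        # monotone with opposite endpoint signs must cross; fall back to ends
        idx = np.asarray([0]) if fa * fb < 0 else idx
    if idx.size == 0:
        raise NumericalError(
            f"no bracket for level {t} on segment ({a},{b}) declared {kind}: "
            f"endpoint values {fa + t:.6g}, {fb + t:.6g}")
    lo_br, hi_br = float(xs[idx[0]]), float(xs[idx[0] + 1])
    return float(optimize.brentq(
        lambda x: float(density.pdf(np.asarray([x]))[0]) - t,
        lo_br, hi_br, xtol=root_tol))


def level_partition(density: DensityModel, t: float,
                    region: IntervalUnion | None = None,
                    at_tol: float = DEFAULT_AT_TOL,
                    root_tol: float = DEFAULT_ROOT_TOL,
                    grid: int = 1024) -> tuple[IntervalUnion, IntervalUnion,
                                               IntervalUnion]:
    """Partition a region into ({p < t}, {p = t}, {p > t}) up to
    measure-zero boundary points.

    The "at" member collects only constant segments whose level matches t
    within ``at_tol`` (relative); isolated crossing points on monotone
    segments have measure zero and are never reported.
    """
    if not (t > 0):
        raise DomainError(f"level must be > 0, got {t}")
    if region is None:
        region = density.whole
    lo, hi = density.support
    if not region.within(lo, hi):
        raise DomainError(f"region {region!r} outside support ({lo},{hi})")

    below: list[tuple[float, float]] = []
    at: list[tuple[float, float]] = []
    above: list[tuple[float, float]] = []

    for seg_lo, seg_hi, kind in density.segments:
        for a, b in region.intersect(seg_lo, seg_hi):
            if kind == CONSTANT:
                h = float(density.pdf(np.asarray([(a + b) / 2
                                                  if math.isfinite(b)
                                                  else a + 1.0]))[0])
                if abs(h - t) <= at_tol * max(t, 1.0):
                    at.append((a, b))
                elif h < t:
                    below.append((a, b))
                else:
                    above.append((a, b))
                continue
            x = _crossing(density, t, a, b, kind, root_tol, grid)
            if x is None or not (a < x < b):
                probe = a + 0.5 * ((b - a) if math.isfinite(b) else 1.0)
                side = float(density.pdf(np.asarray([probe]))[0])
                (below if side < t else above).append((a, b))
            elif kind == DECREASING:
                above.append((a, x))
                below.append((x, b))
            else:  # increasing
                below.append((a, x))
                above.append((x, b))

    return IntervalUnion(below), IntervalUnion(at), IntervalUnion(above)
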