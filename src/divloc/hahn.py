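"""One-step Hahn decomposition of a part under the degree-of-uniformity measure.

For a part A with mass c_A and diversity D_A, the signed measure
m_{D_A/c_A} splits A into the explicit disjoint triple

    P_A = {p < c_A/D_A}   (strictly positive: every subset is strictly more
                           uniform than A),
    Z_A = {p = c_A/D_A}   (null: every subset is exactly as uniform as A),
    N_A = {p > c_A/D_A}   (strictly negative),

each maximal among sets with its property.  Exact equality for Z almost never
survives floating point, so atoms within a relative tolerance band of the
threshold are assigned to Z; ties between the band and a strict side resolve
toward Z, which keeps designed null sets intact under rounding noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

from .continuous import DensityModel, IntervalUnion, level_partition, summarize_region
from .discrete import DiscreteDistribution, DiscretePart, summarize_part
from .errors import DomainError
from .summary import PartSummary

Source = Union[DiscreteDistribution, DensityModel]
Part = Union[DiscretePart, IntervalUnion]

DEFAULT_Z_RTOL = 1e-9

POSITIVE = "strictly_positive"
NEGATIVE = "strictly_negative"
NULL = "null"
MIXED = "mixed"


@dataclass(frozen=True)
class HahnTriple:
    """Result of one Hahn split: parent part, threshold c_A/D_A, and the
    (possibly empty) positive / null / negative members with summaries."""

    parent: Part
    parent_summary: PartSummary
    threshold: float
    positive: Part
    null: Part
    negative: Part
    summaries: dict = field(compare=False)

    def members(self) -> tuple[tuple[str, Part], ...]:
        """The three members in canonical P, Z, N order (including empties)."""
        return (("P", self.positive), ("Z", self.null), ("N", self.negative))


def _is_empty(part: Part) -> bool:
    if isinstance(part, IntervalUnion):
        return part.is_empty
    return len(part) == 0


def _summarize(source: Source, part: Part) -> PartSummary:
    if isinstance(source, DensityModel):
        return summarize_region(source, part)
    return summarize_part(source, part)


def split(source: Source, part: Part | None = None,
          z_rtol: float = DEFAULT_Z_RTOL,
          at_tol: float | None = None,
          root_tol: float = 1e-10) -> HahnTriple:
    """Hahn-decompose a part of a discrete distribution or a region of a
    continuous density at the threshold c_A/D_A."""
    if part is None:
        part = source.whole if isinstance(source, DensityModel) else source.support
    if _is_empty(part):
        raise DomainError("cannot split an empty part")
    summary = _summarize(source, part)
    thr = summary.threshold

    if isinstance(source, DensityModel):
        below, at, above = level_partition(
            source, thr, part,
            at_tol=(at_tol if at_tol is not None else 1e-9),
            root_tol=root_tol)
        pos, zero, neg = below, at, above
    else:
        members = sorted(part, key=lambda lab: (str(type(lab)), lab))
        probs = source.probs_of(members)
        band = z_rtol * thr
        in_z = np.abs(probs - thr) <= band
        pos = frozenset(m for m, p, z in zip(members, probs, in_z)
                        if not z and p < thr)
        zero = frozenset(m for m, z in zip(members, in_z) if z)
        neg = frozenset(m for m, p, z in zip(members, probs, in_z)
                        if not z and p > thr)

    summaries = {name: _summarize(source, member)
                 for name, member in (("P", pos), ("Z", zero), ("N", neg))
                 if not _is_empty(member)}
    return HahnTriple(parent=part, parent_summary=summary, threshold=thr,
                      positive=pos, null=zero, negative=neg,
                      summaries=summaries)


def classify_part(source: Source, part: Part, ref_dou: float,
                  z_rtol: float = DEFAULT_Z_RTOL) -> str:
    """Classify a part as strictly_positive / null / strictly_negative /
    mixed with respect to a reference degree of uniformity.

    A part is strictly positive for the measure m_ref exactly when every
    atom probability (density value) is below the threshold 1/ref_dou,
    strictly negative when every one is above, null when all sit on it.
    """
    if not (ref_dou > 0):
        raise DomainError(f"reference degree of uniformity must be > 0, got {ref_dou}")
    if _is_empty(part):
        raise DomainError("cannot classify an empty part")
    thr = 1.0 / ref_dou

    if isinstance(source, DensityModel):
        below, at, above = level_partition(source, thr, part)
        n_sides = sum(not _is_empty(s) for s in (below, at, above))
        if n_sides > 1:
            return MIXED
        if not _is_empty(below):
            return POSITIVE
        if not _is_empty(above):
            return NEGATIVE
        return NULL

    probs = source.probs_of(part)
    band = z_rtol * thr
    in_z = np.abs(probs - thr) <= band
    if np.all(in_z):
        return NULL
    if np.all(~in_z & (probs < thr)):
        return POSITIVE
    if np.all(~in_z & (probs > thr)):
        return NEGATIVE
    return MIXED


@dataclass(frozen=True)
class MaximalityReport:
    """Brute-force confirmation that a split's members are the unique
    maximal strictly positive / null / strictly negative subsets."""

    confirmed: bool
    n_subsets: int
    counterexamples: tuple = ()


def maximality_oracle(dist: DiscreteDistribution, part: Iterable,
                      m_tol: float = 1e-9,
                      max_atoms: int = 20) -> MaximalityReport:
    """Enumerate every subset of the part, evaluate the signed measure
    m(S) = c_S ln(dou(S)/dou(part)) on each, and confirm that the Hahn
    split's members are maximal for their sign classes.

    Exponential in the part size; refuses parts above ``max_atoms``.
    """
    members = sorted(part, key=lambda lab: (str(type(lab)), lab))
    n = len(members)
    if n == 0:
        raise DomainError("empty part")
    if n > max_atoms:
        raise DomainError(f"part has {n} atoms; oracle limited to {max_atoms}")

    p = np.asarray(dist.probs_of(members), dtype=float)
    parent = summarize_part(dist, members)
    log_ref = math.log(parent.dou)

    size = 1 << n
    c = np.zeros(size)
    plogp = np.zeros(size)
    for s in range(1, size):
        low = s & (s - 1)
        i = (s ^ low).bit_length() - 1
        c[s] = c[low] + p[i]
        plogp[s] = plogp[low] + p[i] * math.log(p[i])
    # H_S = ln c - plogp/c and m(S) = c * (ln dou(S) - ln dou(parent))
    m = np.zeros(size)
    h = np.log(c[1:]) - plogp[1:] / c[1:]
    m[1:] = c[1:] * (h - np.log(c[1:]) - log_ref)

    # sign-class flags, propagated so strictly_* means "all nonempty subsets"
    sp = np.zeros(size, dtype=bool)
    sn = np.zeros(size, dtype=bool)
    nl = np.zeros(size, dtype=bool)
    for s in range(1, size):
        ok_p = m[s] > m_tol
        ok_n = m[s] < -m_tol
        ok_z = abs(m[s]) <= m_tol
        t = s
        while t and (ok_p or ok_n or ok_z):
            bit = t & -t
            sub = s ^ bit
            if sub:
                ok_p = ok_p and sp[sub]
                ok_n = ok_n and sn[sub]
                ok_z = ok_z and nl[sub]
            t ^= bit
        sp[s], sn[s], nl[s] = ok_p, ok_n, ok_z

    triple = split(dist, frozenset(members))

    def mask_of(sub: frozenset) -> int:
        idx = {lab: i for i, lab in enumerate(members)}
        msk = 0
        for lab in sub:
            msk |= 1 << idx[lab]
        return msk

    counter = []
    for name, member, flags in (("positive", triple.positive, sp),
                                ("null", triple.null, nl),
                                ("negative", triple.negative, sn)):
        msk = mask_of(member)
        if msk and not flags[msk]:
            counter.append((name, frozenset(member), "member not in its class"))
        for s in range(1, size):
            if flags[s] and (s & ~msk):
                bad = frozenset(members[i] for i in range(n) if s >> i & 1)
                counter.append((name, bad, "class subset escapes the member"))
                break

    return MaximalityReport(confirmed=not counter, n_subsets=size - 1,
                            counterexamples=tuple(counter))
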