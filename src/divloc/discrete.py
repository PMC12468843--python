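"""Discrete distributions, parts, and the degree-of-uniformity signed measure.

A distribution is a finite set of labeled atoms with probabilities p_i summing
to one.  A *part* is any subset of the labels (not necessarily contiguous).
For a part P with mass c_P = sum of p_i over P, conditional entropy
H_P = -sum (p_i/c_P) ln(p_i/c_P) and diversity D_P = exp(H_P), the ratio
D_P/c_P is the part's degree of uniformity.

The signed measure m_{r}(P) = c_P ln( (D_P/c_P) / r ) compares the part
against a reference degree of uniformity r; it is positive, zero, or negative
exactly when the part is more, equally, or less uniformly distributed than
the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .summary import PartSummary

Label = Hashable
DiscretePart = frozenset

DEFAULT_MASS_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteDistribution:
    """Labeled atoms with strictly positive probabilities summing to one.

    Zero-probability atoms are removed at construction (``dropped_zeros``
    records that this happened), so every part summary is free of 0*ln 0
    terms.  Labels keep insertion order but carry no metric meaning: the
    decomposition never uses label order.
    """

    labels: tuple
    probs: np.ndarray
    dropped_zeros: bool = False
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index",
                           {lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def support(self) -> DiscretePart:
        return frozenset(self.labels)

    def prob(self, label: Label) -> float:
        return float(self.probs[self._index[label]])

    def probs_of(self, part: Iterable[Label]) -> np.ndarray:
        try:
            idx = [self._index[lab] for lab in part]
        except KeyError as exc:
            raise DomainError(f"label {exc.args[0]!r} not in distribution") from exc
        return self.probs[idx]


def make_distribution(labels: Sequence[Label], probs: Sequence[float],
                      tol: float = DEFAULT_MASS_TOL,
                      renormalize: bool = False) -> DiscreteDistribution:
    """Validate and build a :class:`DiscreteDistribution`.

    Parameters
    ----------
    labels, probs : equal-length sequences; labels unique, probs >= 0.
    tol : tolerance on |sum(probs) - 1| (ignored when ``renormalize``).
    renormalize : divide by the total instead of validating it; use for
        count or percentage data.
    """
    if len(labels) != len(probs):
        raise ValidationError(
            f"{len(labels)} labels but {len(probs)} probabilities")
    if len(set(labels)) != len(labels):
        raise ValidationError("labels must be unique")
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValidationError("empty distribution")
    if not np.all(np.isfinite(p)):
        raise ValidationError("probabilities must be finite")
    if np.any(p < 0):
        bad = [labels[i] for i in np.flatnonzero(p < 0)]
        raise ValidationError(f"negative probability at labels {bad}")
    total = float(p.sum())
    if renormalize:
        if total <= 0:
            raise ValidationError("cannot renormalize a zero-total histogram")
        p = p / total
    elif abs(total - 1.0) > tol:
        raise ValidationError(
            f"probabilities sum to {total!r}, not 1 (tol={tol}); "
            "pass renormalize=True for count data")
    keep = p > 0.0
    dropped = bool(np.any(~keep))
    labs = tuple(lab for lab, k in zip(labels, keep) if k)
    return DiscreteDistribution(labels=labs, probs=p[keep],
                                dropped_zeros=dropped)


def summarize_part(dist: DiscreteDistribution,
                   part: Iterable[Label]) -> PartSummary:
    """Mass, conditional entropy, diversity, and degree of uniformity of a part."""
    members = frozenset(part)
    if not members:
        raise DomainError("cannot summarize an empty part")
    p = dist.probs_of(members)
    c = float(p.sum())
    if c <= 0.0:
        raise DomainError("part has zero mass")
    q = p / c
    entropy = float(-(q * np.log(q)).sum())
    return PartSummary.from_mass_entropy(c, entropy)


def uniformity_measure(ref_dou: float, dist: DiscreteDistribution,
                       part: Iterable[Label]) -> float:
    """Signed measure m_r(P) = c_P ln(dou(P) / r) for reference dou r.

    Positive (zero, negative) exactly when the part is more (equally, less)
    uniformly distributed than the reference.
    """
    if not (ref_dou > 0):
        raise DomainError(f"reference degree of uniformity must be > 0, got {ref_dou}")
    s = summarize_part(dist, part)
    return s.mass * math.log(s.dou / ref_dou)


def compare_parts(dist1: DiscreteDistribution, part1: Iterable[Label],
                  dist2: DiscreteDistribution, part2: Iterable[Label]) -> float:
    """Ratio R = dou(part1)/dou(part2): part1 is R times more uniformly
    distributed than part2.  The parts may come from different distributions."""
    s1 = summarize_part(dist1, part1)
    s2 = summarize_part(dist2, part2)
    return s1.dou / s2.dou
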