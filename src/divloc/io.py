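"""Readers and writers for histogram tables and density specifications.

Histograms are CSV/TSV with a header and columns ``label`` plus either
``prob`` (must sum to one) or ``count`` (renormalized).  Densities are JSON
objects like ``{"family": "exponential", "rate": 2.0}`` or
``{"family": "piecewise_constant", "breaks": [...], "heights": [...]}``;
piecewise tables are also accepted as two-column CSV (break, height).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .continuous import DensityModel
from .discrete import DiscreteDistribution, make_distribution
from .errors import ValidationError


def read_histogram(path, renormalize: bool | None = None,
                   tol: float = 1e-9) -> DiscreteDistribution:
    """Read a labeled histogram.  A ``count`` column is always renormalized;
    a ``prob`` column only when ``renormalize`` is set."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "label" not in df.columns:
        raise ValidationError(f"{path}: missing required 'label' column")
    if "prob" in df.columns:
        values = df["prob"]
        renorm = bool(renormalize)
    elif "count" in df.columns:
        values = df["count"]
        renorm = True
    else:
        raise ValidationError(f"{path}: need a 'prob' or 'count' column")
    return make_distribution(list(df["label"]), values.to_numpy(dtype=float),
                             tol=tol, renormalize=renorm)


def write_histogram(dist: DiscreteDistribution, path) -> None:
    pd.DataFrame({"label": list(dist.labels), "prob": dist.probs}) \
        .to_csv(path, index=False)


def density_from_spec(spec: dict) -> DensityModel:
    family = spec.get("family")
    if family == "exponential":
        return DensityModel.exponential(spec["rate"])
    if family == "piecewise_constant":
        return DensityModel.piecewise_constant(spec["breaks"], spec["heights"])
    if family == "uniform":
        return DensityModel.uniform(spec["a"], spec["b"])
    raise ValidationError(f"unknown density family {family!r}")


def density_to_spec(density: DensityModel) -> dict:
    if density.family == "exponential":
        return {"family": "exponential", "rate": density.params[0]}
    if density.family == "piecewise_constant":
        breaks, heights = density.params
        return {"family": "piecewise_constant",
                "breaks": list(breaks), "heights": list(heights)}
    raise ValidationError(f"family {density.family!r} has no JSON form")


def read_density(path) -> DensityModel:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return density_from_spec(json.loads(path.read_text()))
    # CSV table of (break, height) rows; the last row's height is ignored
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"break", "height"} <= set(df.columns):
        raise ValidationError(f"{path}: need 'break' and 'height' columns")
    breaks = df["break"].to_numpy(dtype=float)
    heights = df["height"].to_numpy(dtype=float)[:-1]
    return DensityModel.piecewise_constant(breaks, heights)


def write_density(density: DensityModel, path) -> None:
    Path(path).write_text(json.dumps(density_to_spec(density), indent=1))
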