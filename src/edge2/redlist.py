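"""Extinction-risk weightings: original GE integers and the GE2 curve.

The original EDGE metric weighted Red List categories with integers 0-4.
EDGE2 replaces them with extinction probabilities ``p`` over a 50-year
horizon: CR is anchored at 0.97 and each step down the Red List halves the
risk (EN 0.485, VU 0.2425, NT 0.12125, LC 0.060625).  To express uncertainty
within a category, species are ranked by "true" extinction risk on a
continuous axis x in [0, 1] split into five equal-width category intervals;
a degree-4 polynomial is interpolated through the five (interval midpoint,
anchor) points and clipped to [0.0001, 0.9999] on evaluation.  Sampling a
category draws x uniformly on its interval; DD and NE species draw from the
whole axis.  Because the interpolant is strictly increasing on [0, 1], the
median sampled probability for each data-sufficient category equals its
anchor, and the DD/NE median equals the VU anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .trees import DATA_SUFFICIENT

__all__ = [
    "GE2Curve",
    "build_ge2_curve",
    "ge1_weight",
    "category_median_p",
    "sample_p",
    "protocol_constants",
]

_SAMPLEABLE = set(DATA_SUFFICIENT) | {"EW", "DD", "NE"}


def protocol_constants() -> dict:
    """Load the versioned protocol-constant file shipped with the package."""
    with resources.files("edge2.data").joinpath("protocol_constants.yaml").open() as fh:
        return yaml.safe_load(fh)


_CONST = protocol_constants()


def ge1_weight(category: str) -> int:
    """Original EDGE GE weight: LC 0, NT 1, VU 2, EN 3, CR 4.

    The original metric is defined only for data-sufficient categories;
    DD, NE, EW and EX raise ``ValueError``.
    """
    weights = _CONST["ge1_weights"]
    if category not in weights:
        raise ValueError(
            f"GE is undefined for category {category!r}; the original EDGE "
            "metric covers data-sufficient categories LC..CR only"
        )
    return int(weights[category])


@dataclass(frozen=True)
class GE2Curve:
    """The clipped quartic rank -> extinction-probability model.

    ``coefficients`` are in ascending power order over rank x in [0, 1];
    evaluation clips to ``[clip_lower, clip_upper]``.
    """

    coefficients: tuple[float, ...]
    anchors: dict[str, float]
    rank_intervals: dict[str, tuple[float, float]]
    clip_lower: float
    clip_upper: float
    ew_probability: float
    version: int

    def evaluate_raw(self, x):
        """The unclipped polynomial at rank x."""
        return np.polynomial.polynomial.polyval(
            np.asarray(x, dtype=float), np.asarray(self.coefficients)
        )

    def evaluate(self, x):
        """Clipped probability at rank x (vectorised)."""
        return np.clip(self.evaluate_raw(x), self.clip_lower, self.clip_upper)

    def median_p(self, category: str) -> float:
        """Median sampled probability for a data-sufficient category.

        Under uniform-in-rank sampling on a monotone segment this is the
        curve at the interval midpoint, which reproduces the anchor.
        """
        if category not in DATA_SUFFICIENT:
            raise ValueError(
                f"category {category!r} has no single median probability; "
                "use sample_p for DD/NE"
            )
        lo, hi = self.rank_intervals[category]
        return float(self.evaluate((lo + hi) / 2.0))

    def sample(self, category: str, rng: np.random.Generator, size=None):
        """Draw extinction probabilities for one category.

        Data-sufficient categories draw rank uniformly on their interval;
        DD and NE draw from the full [0, 1] axis; EW is pinned at the upper
        clip bound.  EX is not scored and raises ``ValueError``.
        """
        if category == "EX":
            raise ValueError("EX taxa are not scored")
        if category not in _SAMPLEABLE:
            raise ValueError(f"cannot sample p for category {category!r}")
        if category == "EW":
            p = self.ew_probability
            if size is None:
                return float(p)
            return np.full(size, p, dtype=float)
        if category in ("DD", "NE"):
            lo, hi = 0.0, 1.0
        else:
            lo, hi = self.rank_intervals[category]
        x = rng.uniform(lo, hi, size=size)
        out = self.evaluate(x)
        if size is None:
            return float(out)
        return out


def build_ge2_curve() -> GE2Curve:
    """Interpolate the degree-4 curve through the five category anchors."""
    anchors = {k: float(v) for k, v in _CONST["anchors"].items()}
    intervals = {
        k: (float(v[0]), float(v[1])) for k, v in _CONST["rank_intervals"].items()
    }
    xs = np.array([(lo + hi) / 2.0 for lo, hi in (intervals[c] for c in DATA_SUFFICIENT)])
    ys = np.array([anchors[c] for c in DATA_SUFFICIENT])
    coef = np.polynomial.polynomial.polyfit(xs, ys, 4)
    return GE2Curve(
        coefficients=tuple(float(c) for c in coef),
        anchors=anchors,
        rank_intervals=intervals,
        clip_lower=float(_CONST["clip_lower"]),
        clip_upper=float(_CONST["clip_upper"]),
        ew_probability=float(_CONST["ew_probability"]),
        version=int(_CONST["version"]),
    )


def category_median_p(category: str, curve: GE2Curve | None = None) -> float:
    """Anchor (median) extinction probability for a data-sufficient category."""
    if curve is None:
        curve = build_ge2_curve()
    return curve.median_p(category)


def sample_p(
    category: str,
    curve: GE2Curve,
    rng: np.random.Generator,
    size=None,
):
    """Draw extinction probabilities; see :meth:`GE2Curve.sample`."""
    return curve.sample(category, rng, size=size)
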