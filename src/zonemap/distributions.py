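"""Per-gene distribution descriptors: ECDFs, quartiles, half-widths.

Every statistic here works on the unbinned sample — sorting the coordinate
values and using their normalized ordinal number as the cumulative fraction
loses no information, unlike a histogram.  The half-width (Q3 - Q1) is the
measure of a zone's broadness, and the maximal vertical distance between
two ECDFs is the measure of how different two zones are; it coincides with
the two-sample Kolmogorov-Smirnov statistic D.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .coordinates import coordinate_samples

__all__ = [
    "ECDF",
    "GeneDistribution",
    "ecdf",
    "quartiles",
    "half_width",
    "ks_distance",
    "distance_range",
    "histogram",
    "summarize",
    "ellipse_specs",
    "percent",
    "COORDINATES",
]

COORDINATES = ("laminar", "radial", "z")


class ECDF:
    """Empirical cumulative distribution function of a sample.

    A right-continuous step function: F(x) = (# values <= x) / n.  Ties
    accumulate into a single step of height k/n at the tied value.
    """

    def __init__(self, values):
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("ECDF requires at least one observation")
        if np.any(np.isnan(values)):
            raise ValueError("ECDF sample contains NaN")
        self.n = values.size
        self.x, counts = np.unique(values, return_counts=True)
        self.y = np.cumsum(counts) / self.n

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(self.x, q, side="right")
        padded = np.concatenate(([0.0], self.y))
        return padded[idx]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ECDF)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ECDF(n={self.n}, support=[{self.x[0]:g}, {self.x[-1]:g}])"


def ecdf(values) -> ECDF:
    """ECDF of a non-empty sample (ties merge into one step)."""
    return ECDF(values)


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take quartiles of an empty sample")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def half_width(q1: float, q3: float) -> float:
    """Interquartile width Q3 - Q1, the broadness of a distribution."""
    if q1 > q3:
        raise ValueError(f"q1 ({q1}) exceeds q3 ({q3})")
    return q3 - q1


def ks_distance(a: ECDF, b: ECDF) -> float:
    """Maximal vertical distance sup_x |F_a(x) - F_b(x)|.

    The supremum of a difference of step functions is attained at a step
    point, so evaluating both ECDFs on the union of their supports is exact.
    """
    if not isinstance(a, ECDF):
        a = ECDF(a)
    if not isinstance(b, ECDF):
        b = ECDF(b)
    grid = np.union1d(a.x, b.x)
    return float(np.max(np.abs(a(grid) - b(grid))))


def percent(x: float, decimals: int = 1) -> float:
    """Fraction as a percentage, rounded half away from zero."""
    scaled = x * 100.0 * 10**decimals
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return float(rounded / 10**decimals)


def distance_range(
    samples: dict[str, np.ndarray], as_percent: bool = True
) -> tuple[float, float]:
    """(min, max) maximal vertical distance over all unordered gene pairs."""
    if len(samples) < 2:
        raise ValueError("need at least two genes to compare")
    curves = {g: ECDF(v) for g, v in samples.items()}
    dists = [
        ks_distance(curves[a], curves[b]) for a, b in combinations(sorted(curves), 2)
    ]
    lo, hi = min(dists), max(dists)
    if as_percent:
        return percent(lo), percent(hi)
    return lo, hi


def histogram(values, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Counts over equal-width bins on [0, 1] (display only; statistics are
    always computed on the unbinned sample)."""
    if n_bins < 1:
        raise ValueError("need at least one bin")
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return counts, edges


@dataclass
class GeneDistribution:
    """Descriptors of one gene's distribution along one coordinate."""

    gene: str
    coordinate: str
    sample: np.ndarray
    per_organ: dict[str, np.ndarray]
    q1: float
    median: float
    q3: float

    @property
    def n(self) -> int:
        return int(self.sample.size)

    @property
    def half_width(self) -> float:
        return half_width(self.q1, self.q3)

    @property
    def ecdf(self) -> ECDF:
        return ECDF(self.sample)

    def organ_ecdfs(self) -> dict[str, ECDF]:
        return {o: ECDF(v) for o, v in self.per_organ.items() if v.size}


def summarize(
    normalized: pd.DataFrame,
    genes: list[str] | None = None,
    coordinates: tuple[str, ...] = COORDINATES,
) -> dict[tuple[str, str], GeneDistribution]:
    """Pooled descriptors per gene x coordinate, keeping per-organ samples.

    Statistics are computed on cells pooled over organs; the per-organ
    samples are retained only for the grey overlay curves.  A gene with no
    usable cells for a coordinate is omitted (and recorded in the result's
    ``attrs``-free return by simply being absent).
    """
    if genes is None:
        genes = sorted(normalized["gene"].unique())
    out: dict[tuple[str, str], GeneDistribution] = {}
    for gene in genes:
        sub = normalized[normalized["gene"] == gene]
        for coord in coordinates:
            pooled = coordinate_samples(sub, gene, coord)
            if pooled.size == 0:
                continue
            col = {"laminar": "h_rel", "radial": "r_rel", "z": "z_rel"}[coord]
            per_organ = {
                organ: grp[col].dropna().to_numpy(float)
                for organ, grp in sub.groupby("organ_id")
            }
            q1, med, q3 = quartiles(pooled)
            out[(gene, coord)] = GeneDistribution(
                gene, coord, pooled, per_organ, q1, med, q3
            )
    return out


def descriptor_table(
    distributions: dict[tuple[str, str], GeneDistribution]
) -> pd.DataFrame:
    """Tabular view: gene, coordinate, n, q1, median, q3, half_width."""
    rows = [
        (d.gene, d.coordinate, d.n, d.q1, d.median, d.q3, d.half_width)
        for d in distributions.values()
    ]
    return pd.DataFrame(
        rows, columns=["gene", "coordinate", "n", "q1", "median", "q3", "half_width"]
    ).sort_values(["coordinate", "gene"], ignore_index=True)


def ellipse_specs(
    distributions: dict[tuple[str, str], GeneDistribution],
    x_coordinate: str = "radial",
    y_coordinate: str = "laminar",
) -> pd.DataFrame:
    """Quartile-ellipse summary for a coordinate pair.

    Each gene becomes an ellipse centered on its (x, y) medians whose axis
    extents run from the 1st to the 3rd quartile, i.e. the extent along each
    axis equals that coordinate's half-width.
    """
    genes = sorted(
        {g for (g, c) in distributions if c == x_coordinate}
        & {g for (g, c) in distributions if c == y_coordinate}
    )
    rows = []
    for gene in genes:
        dx = distributions[(gene, x_coordinate)]
        dy = distributions[(gene, y_coordinate)]
        rows.append(
            (gene, dx.median, dy.median, dx.q1, dx.q3, dy.q1, dy.q3,
             dx.half_width, dy.half_width)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "x_center", "y_center", "x_q1", "x_q3", "y_q1", "y_q3",
            "x_extent", "y_extent",
        ],
    )


def median_span_percent(medians, decimals: int = 0) -> float:
    """Spread between the extreme medians as a percentage of the full axis.

    With the laminar medians of the sparse genes this is the 'difference in
    median height between the most apical and the most basal receptor' line
    of the descriptor report, quoted as a whole percentage by default.
    """
    medians = np.asarray(list(medians), dtype=float)
    if medians.size < 2:
        raise ValueError("need at least two medians")
    return percent(float(medians.max() - medians.min()), decimals=decimals)
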