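"""Model/results interface over the zone-mapping pipeline.

`ZoneModel` holds a normalized cell table together with the gene roles
(sparse receptors, broadly expressed co-receptor, cell-type markers);
`fit()` runs the descriptive statistics and every pairwise comparison and
returns a `ZoneResults` carrying the descriptor table, the per-coordinate
D and p matrices, the per-coordinate groups, the combined zone partition
and the marker contrasts, with a `summary()` in the usual fitted-model
style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compare, coordinates, distributions
from .compare import ComparisonMatrix, ZonePartition
from .distributions import COORDINATES, GeneDistribution
from .simulate import CORECEPTOR_GENE, MARKER_GENES, SPARSE_GENES

__all__ = ["ZoneModel", "ZoneResults"]


class ZoneModel:
    """Spatial expression-zone model over a table of normalized cells.

    Parameters
    ----------
    normalized
        Table with columns organ_id, gene, section_index, h_rel, r_rel
        (NaN when radially excluded), z_rel.
    sparse_genes
        Genes entering the pairwise zone analysis.  Defaults to whichever
        of the canonical sparse receptors are present; if none are, every
        non-marker gene in the table.
    coreceptor, markers
        Broadly expressed genes used only in the marker contrasts.
    """

    def __init__(
        self,
        normalized: pd.DataFrame,
        sparse_genes: tuple[str, ...] | None = None,
        coreceptor: str | None = CORECEPTOR_GENE,
        markers: tuple[str, ...] = MARKER_GENES,
    ):
        if normalized.empty:
            raise ValueError("normalized cell table is empty")
        self.data = normalized.reset_index(drop=True)
        present = set(self.data["gene"].unique())
        if sparse_genes is None:
            sparse_genes = tuple(g for g in SPARSE_GENES if g in present)
            if not sparse_genes:
                excluded = set(markers) | {coreceptor}
                sparse_genes = tuple(sorted(present - excluded))
        missing = set(sparse_genes) - present
        if missing:
            raise ValueError(f"sparse genes absent from table: {sorted(missing)}")
        self.sparse_genes = tuple(sparse_genes)
        self.coreceptor = coreceptor if coreceptor in present else None
        self.markers = tuple(m for m in markers if m in present)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ZoneModel":
        """Build from a normalized table (alias of the constructor)."""
        return cls(df, **kwargs)

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        min_length: float | None = None,
        lenient: bool = False,
        **kwargs,
    ) -> "ZoneModel":
        """Build from raw measurements, normalizing them first."""
        norm_kwargs = {} if min_length is None else {"min_length": min_length}
        normalized = coordinates.normalize_table(raw, lenient=lenient, **norm_kwargs)
        return cls(normalized, **kwargs)

    def coordinate_sample(self, gene: str, coordinate: str) -> np.ndarray:
        return coordinates.coordinate_samples(self.data, gene, coordinate)

    def fit(
        self,
        alpha: float = compare.DEFAULT_ALPHA,
        method: str = "asymptotic",
        seed: int | None = None,
    ) -> "ZoneResults":
        """Run descriptors, pairwise KS matrices and the zone partition."""
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        dists = distributions.summarize(self.data)
        matrices: dict[str, ComparisonMatrix] = {}
        for coord in COORDINATES:
            samples = {
                g: self.coordinate_sample(g, coord) for g in self.sparse_genes
            }
            matrices[coord] = compare.pairwise_matrix(
                samples, coord, alpha=alpha, method=method, seed=seed
            )
        partition = compare.zone_partition(matrices)
        contrasts = compare.marker_contrasts(
            self.data,
            sparse_genes=self.sparse_genes,
            coreceptor=self.coreceptor or CORECEPTOR_GENE,
            markers=self.markers if len(self.markers) == 2 else MARKER_GENES,
            alpha=alpha,
        )
        return ZoneResults(self, alpha, method, dists, matrices, partition, contrasts)


@dataclass
class ZoneResults:
    """Fitted zone map: descriptors, comparison matrices, partition."""

    model: ZoneModel
    alpha: float
    method: str
    distributions: dict[tuple[str, str], GeneDistribution]
    matrices: dict[str, ComparisonMatrix]
    partition: ZonePartition
    marker_contrasts: pd.DataFrame

    @property
    def descriptors(self) -> pd.DataFrame:
        return distributions.descriptor_table(self.distributions)

    @property
    def zone_count(self) -> int:
        return self.partition.zone_count

    def groups(self, coordinate: str) -> list[tuple[str, ...]]:
        return self.partition.groups[coordinate]

    def distance_range(self, coordinate: str, as_percent: bool = True) -> tuple[float, float]:
        """(min, max) maximal vertical distance over sparse-gene pairs."""
        m = self.matrices[coordinate]
        off = m.d.values[np.triu_indices(len(m.genes), k=1)]
        lo, hi = float(off.min()), float(off.max())
        if as_percent:
            return distributions.percent(lo), distributions.percent(hi)
        return lo, hi

    def median_span_percent(self, coordinate: str = "laminar", decimals: int = 0) -> float:
        """Spread of the sparse genes' medians, as percent of the axis."""
        medians = [
            self.distributions[(g, coordinate)].median
            for g in self.model.sparse_genes
        ]
        return distributions.median_span_percent(medians, decimals=decimals)

    def ellipses(self, x_coordinate: str = "radial", y_coordinate: str = "laminar") -> pd.DataFrame:
        return distributions.ellipse_specs(
            self.distributions, x_coordinate, y_coordinate
        )

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Spatial expression-zone analysis")
        add("=" * 48)
        n_cells = len(self.model.data)
        add(f"cells: {n_cells}   genes: {len(set(self.model.data['gene']))}   "
            f"sparse genes: {len(self.model.sparse_genes)}")
        add(f"KS method: {self.method}   significance cutoff: p < {self.alpha:g}")
        add("")
        add("Distribution descriptors (pooled over organs)")
        add(self.descriptors.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        add("")
        lam = [self.distributions[(g, "laminar")].median for g in self.model.sparse_genes]
        add(f"laminar median range: {min(lam):.3f}-{max(lam):.3f} "
            f"(spread {self.median_span_percent('laminar'):.0f}% of layer height)")
        for coord in COORDINATES:
            lo, hi = self.distance_range(coord)
            add(f"{coord}: max vertical distance between sparse genes {lo:.1f}-{hi:.1f}%")
        add("")
        for coord in COORDINATES:
            groups = " | ".join(",".join(g) for g in self.groups(coord))
            add(f"{coord} groups (maximal cliques): {groups}")
        zones = " | ".join(",".join(z) for z in self.partition.zones)
        add(f"combined zones ({self.zone_count}): {zones}")
        if not self.marker_contrasts.empty:
            add("")
            add("Marker contrasts")
            add(self.marker_contrasts.to_string(
                index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def plot_ecdf(self, coordinate: str = "laminar", **kwargs):
        from . import plotting

        return plotting.plot_ecdfs(self.distributions, coordinate, **kwargs)

    def plot_ellipses(self, x_coordinate: str = "radial", y_coordinate: str = "laminar", **kwargs):
        from . import plotting

        return plotting.plot_ellipses(
            self.ellipses(x_coordinate, y_coordinate),
            x_coordinate, y_coordinate, **kwargs
        )
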