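"""Pairwise two-sample KS testing and the zone partition of genes.

Distributions are compared with the two-sample Kolmogorov-Smirnov test on
the unbinned samples, with raw p < 0.01 as the significance cutoff (the
test is sensitive at the sample sizes involved, n > 100, so a conservative
cutoff replaces any multiple-testing correction).  Genes whose
distributions cannot be told apart in a coordinate form groups — maximal
cliques of the per-coordinate indistinguishability graph, which may
overlap.  Combining all coordinates, two genes share an expression zone
only if no coordinate separates them; the zones are the connected
components of that all-coordinate graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .coordinates import coordinate_samples
from .distributions import COORDINATES, ECDF, ks_distance
from .simulate import CORECEPTOR_GENE, MARKER_GENES, SPARSE_GENES

__all__ = [
    "ks_test",
    "permutation_ks_test",
    "ComparisonMatrix",
    "pairwise_matrix",
    "coordinate_groups",
    "ZonePartition",
    "zone_partition",
    "marker_contrasts",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01


def ks_test(sample_a, sample_b, method: str = "asymptotic", n_permutations: int = 10000,
            seed: int | None = None) -> tuple[float, float]:
    """Two-sample KS test; returns (D, p).

    D is the maximal vertical distance between the two ECDFs.  The
    asymptotic p-value comes from the Kolmogorov limit distribution at
    ``sqrt(en) * D`` with effective size ``en = na*nb/(na+nb)``; the
    permutation method estimates p by seeded label shuffles and serves as
    the small-sample / verification route.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    d = ks_distance(ECDF(a), ECDF(b))
    if method == "asymptotic":
        en = a.size * b.size / (a.size + b.size)
        p = float(np.clip(kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    elif method == "permutation":
        p = permutation_ks_test(a, b, d, n_permutations, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return d, p


def permutation_ks_test(a, b, d_obs: float, n_permutations: int = 10000,
                        seed: int | None = None, chunk: int = 2048) -> float:
    """Permutation p-value: fraction of label shuffles with D >= observed.

    Uses the add-one estimator (B+1 in the denominator) so p is never
    exactly zero.  D under each shuffle is evaluated at the ends of tie
    groups of the pooled sorted sample, which is exact for step functions.
    """
    rng = np.random.default_rng(seed)
    pooled = np.sort(np.concatenate([a, b]))
    n, na, nb = pooled.size, a.size, b.size
    # evaluation points: last index of each tie group
    last = np.flatnonzero(np.diff(pooled, append=np.inf) != 0)
    base = np.zeros(n, dtype=bool)
    base[:na] = True
    exceed = 0
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        masks = rng.permuted(np.tile(base, (m, 1)), axis=1)
        cum_a = np.cumsum(masks, axis=1)[:, last]
        ranks = (last + 1)[None, :]
        d_perm = np.max(np.abs(cum_a / na - (ranks - cum_a) / nb), axis=1)
        exceed += int(np.sum(d_perm >= d_obs - 1e-12))
        done += m
    return (1 + exceed) / (n_permutations + 1)


@dataclass
class ComparisonMatrix:
    """Symmetric pairwise D and p matrices over genes for one coordinate."""

    coordinate: str
    genes: list[str]
    d: pd.DataFrame
    p: pd.DataFrame
    alpha: float = DEFAULT_ALPHA

    def significant(self, a: str, b: str) -> bool:
        return bool(self.p.loc[a, b] < self.alpha)

    def indistinguishability_graph(self) -> nx.Graph:
        """Graph with an edge between genes the test cannot tell apart."""
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for a, b in combinations(self.genes, 2):
            if not self.significant(a, b):
                g.add_edge(a, b)
        return g


def pairwise_matrix(
    samples: dict[str, np.ndarray],
    coordinate: str,
    alpha: float = DEFAULT_ALPHA,
    method: str = "asymptotic",
    seed: int | None = None,
) -> ComparisonMatrix:
    """All unordered gene pairs tested; raw p against alpha (no correction).

    Genes with empty samples are dropped with a warning attribute rather
    than poisoning the matrix.
    """
    import warnings

    usable = {}
    for gene in sorted(samples):
        v = np.asarray(samples[gene], dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            warnings.warn(f"gene {gene} has no usable {coordinate} sample; excluded")
            continue
        usable[gene] = v
    genes = list(usable)
    if len(genes) < 2:
        raise ValueError("need at least two genes with non-empty samples")
    d = pd.DataFrame(0.0, index=genes, columns=genes)
    p = pd.DataFrame(1.0, index=genes, columns=genes)
    for i, (a, b) in enumerate(combinations(genes, 2)):
        pair_seed = None if seed is None else (seed + i) % (2**31)
        dv, pv = ks_test(usable[a], usable[b], method=method, seed=pair_seed)
        d.loc[a, b] = d.loc[b, a] = dv
        p.loc[a, b] = p.loc[b, a] = pv
    return ComparisonMatrix(coordinate, genes, d, p, alpha)


def coordinate_groups(matrix: ComparisonMatrix) -> list[tuple[str, ...]]:
    """Maximal cliques of the indistinguishability graph for one coordinate.

    A gene may belong to several groups (a distribution can be intermediate
    between two otherwise-distinct neighbours).  Deterministic order:
    members sorted within each group, groups sorted lexicographically.
    """
    graph = matrix.indistinguishability_graph()
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    return sorted(cliques)


@dataclass
class ZonePartition:
    """Per-coordinate groups plus the combined disjoint expression zones."""

    groups: dict[str, list[tuple[str, ...]]]
    zones: list[tuple[str, ...]]

    @property
    def zone_count(self) -> int:
        return len(self.zones)

    def to_dict(self) -> dict:
        return {
            "per_coordinate_groups": {
                c: [list(g) for g in gs] for c, gs in self.groups.items()
            },
            "zones": [list(z) for z in self.zones],
            "zone_count": self.zone_count,
        }


def zone_partition(matrices: dict[str, ComparisonMatrix]) -> ZonePartition:
    """Combine per-coordinate tests into disjoint expression zones.

    Two genes stay connected only if they are indistinguishable in every
    coordinate; zones are the connected components of the resulting graph,
    so a chain of pairwise-similar genes collapses into one zone.
    """
    gene_sets = {frozenset(m.genes) for m in matrices.values()}
    if len(gene_sets) != 1:
        raise ValueError("all coordinate matrices must cover the same gene set")
    genes = sorted(next(iter(gene_sets)))
    combined = nx.Graph()
    combined.add_nodes_from(genes)
    for a, b in combinations(genes, 2):
        if all(not m.significant(a, b) for m in matrices.values()):
            combined.add_edge(a, b)
    zones = sorted(tuple(sorted(c)) for c in nx.connected_components(combined))
    groups = {c: coordinate_groups(m) for c, m in sorted(matrices.items())}
    return ZonePartition(groups, zones)


def marker_contrasts(
    normalized: pd.DataFrame,
    sparse_genes: tuple[str, ...] = SPARSE_GENES,
    coreceptor: str = CORECEPTOR_GENE,
    markers: tuple[str, ...] = MARKER_GENES,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Contrasts of receptor distributions against the cell-type markers.

    Laminar: every sparse gene against omp (ciliated marker, expected more
    basal) and against trpc2 (microvillous marker); radial: the co-receptor
    against trpc2.  Missing markers are skipped with a warning.
    """
    import warnings

    present = set(normalized["gene"].unique())
    rows = []

    def add(a: str, b: str, coord: str):
        if a not in present or b not in present:
            warnings.warn(f"marker contrast {a} vs {b} skipped: gene missing")
            return
        sa = coordinate_samples(normalized, a, coord)
        sb = coordinate_samples(normalized, b, coord)
        if sa.size == 0 or sb.size == 0:
            warnings.warn(f"marker contrast {a} vs {b} skipped: empty sample")
            return
        d, p = ks_test(sa, sb)
        rows.append((a, b, coord, d, p, p < alpha))

    omp, trpc2 = markers
    for gene in sparse_genes:
        add(gene, omp, "laminar")
    for gene in sparse_genes:
        add(gene, trpc2, "laminar")
    add(coreceptor, trpc2, "radial")
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "coordinate", "d", "p", "significant"]
    )
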