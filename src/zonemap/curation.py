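"""Curation filters for a candidate olfactory receptor gene family.

Genome-wide homology searches over-report candidate receptor genes:
assembly artifacts duplicate loci, haplotypes masquerade as paralogs, and
distant relatives creep into the hit list.  This module implements the
acceptance filters that reduce raw candidates to bona fide unique family
members: gap-heavy alignment columns are stripped, near-identical sequences
(>98% amino-acid identity) are collapsed as allelic variants, remaining
differences must be distributed along the sequence rather than clustered,
each gene must occupy a unique non-overlapping genomic position, and each
must sit inside the family clade of the phylogenetic tree with branch
support over 80%.  The alignment and the tree are inputs (products of MAFFT
and a maximum-likelihood inference); only the filters are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "Alignment",
    "read_alignment",
    "strip_gap_columns",
    "pairwise_identity",
    "collapse_alleles",
    "distributed_difference",
    "overlap_filter",
    "support_filter",
    "curate",
    "synthetic_family",
]

GAP = "-"
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneModel:
    """A candidate gene: sequence plus a 0-based half-open genomic interval."""

    name: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty or inverted interval")
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")


class Alignment(dict):
    """Gapped amino-acid alignment: name -> row, all rows the same length."""

    def __init__(self, rows: dict[str, str]):
        if not rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        super().__init__(rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.values())))


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file."""
    return Alignment({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")})


def strip_gap_columns(alignment: Alignment, gap_fraction_threshold: float = 0.90) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds the threshold.

    A column that is exactly at the threshold (e.g. 9 gaps in 10 rows at
    0.90) is retained; row order is preserved.  Idempotent.
    """
    names = list(alignment)
    matrix = np.array([list(alignment[n]) for n in names])
    gap_frac = (matrix == GAP).mean(axis=0)
    keep = gap_frac <= gap_fraction_threshold
    return Alignment({n: "".join(row[keep]) for n, row in zip(names, matrix)})


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over positions where neither row is a gap."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    comparable = (a != GAP.encode()) & (b != GAP.encode())
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no mutually ungapped positions to compare")
    return 100.0 * float((a[comparable] == b[comparable]).sum()) / n


def _representative(names, alignment: Alignment) -> str:
    """Longest ungapped sequence; ties broken by name."""
    return min(names, key=lambda n: (-len(alignment[n].replace(GAP, "")), n))


def collapse_alleles(
    alignment: Alignment, identity_threshold: float = 98.0
) -> list[dict]:
    """Single-linkage clusters over the >threshold identity relation.

    Sequences more than ``identity_threshold`` percent identical are treated
    as allelic variants of one gene.  Returns one dict per cluster with the
    members and the chosen representative.
    """
    graph = nx.Graph()
    graph.add_nodes_from(alignment)
    for a, b in combinations(sorted(alignment), 2):
        if pairwise_identity(alignment[a], alignment[b]) > identity_threshold:
            graph.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        clusters.append(
            {"members": members, "representative": _representative(members, alignment)}
        )
    return sorted(clusters, key=lambda c: c["representative"])


def distributed_difference(
    seq_a: str,
    seq_b: str,
    min_diff_pct: float = 2.0,
    span_fraction: float = 0.5,
) -> tuple[bool, str]:
    """Check that two sequences differ enough, and all along the sequence.

    Accepted iff the difference is at least ``min_diff_pct`` percent AND the
    mismatching positions span at least ``span_fraction`` of the alignment
    length (span = last variable column - first variable column + 1).
    Differences concentrated in one stretch are the signature of a chimeric
    or mis-assembled prediction rather than a distinct gene.
    """
    identity = pairwise_identity(seq_a, seq_b)
    diff = 100.0 - identity
    if diff < min_diff_pct:
        return False, f"difference {diff:.2f}% below {min_diff_pct}%"
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    comparable = (a != GAP.encode()) & (b != GAP.encode())
    variable = np.flatnonzero(comparable & (a != b))
    span = int(variable[-1] - variable[0] + 1)
    needed = span_fraction * len(seq_a)
    if span < needed:
        return False, f"variable positions span {span} columns < {needed:.0f}"
    return True, f"difference {diff:.2f}% spanning {span} columns"


def overlap_filter(models: list[GeneModel]) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Flag candidates whose intervals overlap on the same chromosome/strand.

    Intervals are 0-based half-open, so abutting intervals do not conflict.
    Returns (accepted models, list of conflicting name pairs); every model
    in a conflict is excluded from the accepted set.
    """
    conflicts = []
    conflicted: set[str] = set()
    for a, b in combinations(sorted(models, key=lambda m: m.name), 2):
        if a.chrom == b.chrom and a.strand == b.strand:
            if a.start < b.end and b.start < a.end:
                conflicts.append((a.name, b.name))
                conflicted |= {a.name, b.name}
    accepted = [m for m in models if m.name not in conflicted]
    return accepted, conflicts


def _node_support(node) -> float | None:
    label = node.label
    if label is None and node.taxon is not None:
        label = node.taxon.label
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def support_filter(
    tree: "dendropy.Tree | str",
    anchors: list[str],
    candidates: list[str],
    min_support: float = 80.0,
) -> dict[str, list[str]]:
    """Place candidates relative to the family clade of a support-labeled tree.

    The family clade is the smallest clade containing every anchor taxon.
    A candidate outside it is rejected.  Inside it, the candidate's evidence
    of membership is the support of the smallest clade containing the
    candidate and at least one anchor: strictly above ``min_support`` means
    accepted, at or below (or unlabeled) means unresolved.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(
            data=tree, schema="newick", suppress_internal_node_taxa=True
        )
        tree.is_rooted = True
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [a for a in anchors if a not in leaf_names]
    if missing:
        raise ValueError(f"anchor taxa absent from tree: {missing}")
    taxa = [tree.taxon_namespace.get_taxon(a) for a in anchors]
    mrca = tree.mrca(taxa=taxa)
    family_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    anchor_set = set(anchors)
    result: dict[str, list[str]] = {"accepted": [], "unresolved": [], "rejected": []}
    leaf_by_name = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    for name in candidates:
        if name not in leaf_names:
            raise ValueError(f"candidate {name} absent from tree")
        if name not in family_leaves:
            result["rejected"].append(name)
            continue
        node = leaf_by_name[name].parent_node
        while node is not None:
            members = {leaf.taxon.label for leaf in node.leaf_iter()}
            if members & anchor_set:
                support = _node_support(node)
                if support is not None and support > min_support:
                    result["accepted"].append(name)
                else:
                    result["unresolved"].append(name)
                break
            node = node.parent_node
        else:  # pragma: no cover - mrca membership guarantees a hit
            result["rejected"].append(name)
    return {k: sorted(v) for k, v in result.items()}


def curate(
    alignment: Alignment,
    loci: dict[str, tuple[str, int, int, str]],
    tree,
    anchors: list[str],
    candidates: list[str] | None = None,
    gap_fraction_threshold: float = 0.90,
    identity_threshold: float = 98.0,
    min_diff_pct: float = 2.0,
    span_fraction: float = 0.5,
    min_support: float = 80.0,
) -> dict:
    """Run the full acceptance chain and report per-candidate outcomes.

    Order: strip gap-heavy columns; collapse allelic variants; demand
    distributed >=2% differences between cluster representatives (pairs
    failing it are merged like alleles); drop candidates at overlapping
    loci; keep only candidates inside the well-supported family clade.
    Returns the accepted names plus a per-candidate report table.

    ``candidates`` restricts the chain to a subset of the alignment (e.g.
    excluding outgroup taxa that are present only to root the tree); by
    default every aligned sequence is a candidate.
    """
    stripped = strip_gap_columns(alignment, gap_fraction_threshold)
    if candidates is not None:
        missing = set(candidates) - set(stripped)
        if missing:
            raise ValueError(f"candidates absent from alignment: {sorted(missing)}")
        stripped = Alignment({n: stripped[n] for n in candidates})
    clusters = collapse_alleles(stripped, identity_threshold)
    status: dict[str, dict] = {
        name: {"candidate": name, "allele_of": None, "distinct": True,
               "overlap_conflict": False, "clade_status": None, "accepted": False}
        for name in stripped
    }
    reps = []
    for cluster in clusters:
        rep = cluster["representative"]
        reps.append(rep)
        for member in cluster["members"]:
            if member != rep:
                status[member]["allele_of"] = rep

    # merge representative pairs whose differences are too few or clustered
    merge = nx.Graph()
    merge.add_nodes_from(reps)
    reasons: dict[tuple[str, str], str] = {}
    for a, b in combinations(sorted(reps), 2):
        ok, reason = distributed_difference(
            stripped[a], stripped[b], min_diff_pct, span_fraction
        )
        reasons[(a, b)] = reason
        if not ok:
            merge.add_edge(a, b)
    survivors = []
    for comp in nx.connected_components(merge):
        rep = _representative(sorted(comp), stripped)
        survivors.append(rep)
        for member in comp:
            if member != rep:
                status[member]["distinct"] = False
                status[member]["allele_of"] = status[member]["allele_of"] or rep
    survivors.sort()

    models = []
    for name in survivors:
        if name not in loci:
            raise ValueError(f"no genomic locus for candidate {name}")
        chrom, start, end, strand = loci[name]
        models.append(GeneModel(name, stripped[name].replace(GAP, ""), chrom, start, end, strand))
    positioned, conflicts = overlap_filter(models)
    for a, b in conflicts:
        status[a]["overlap_conflict"] = True
        status[b]["overlap_conflict"] = True

    placement = support_filter(tree, anchors, [m.name for m in positioned], min_support)
    for outcome, names in placement.items():
        for name in names:
            status[name]["clade_status"] = outcome
    accepted = sorted(placement["accepted"])
    for name in accepted:
        status[name]["accepted"] = True
    report = pd.DataFrame(list(status.values())).sort_values("candidate", ignore_index=True)
    return {
        "accepted": accepted,
        "clusters": clusters,
        "overlap_conflicts": conflicts,
        "placement": placement,
        "pair_reasons": reasons,
        "report": report,
    }


def synthetic_family(seed: int = 0, n_distinct: int = 17, length: int = 300) -> dict:
    """Synthetic candidate family with known planted structure (test data).

    Builds ``n_distinct`` mutually distinct genes derived from one ancestral
    sequence, then plants: two allelic variants (copies of the first two
    genes with <2% scattered differences), one overlapping locus pair (the
    last two distinct genes share ground), and one low-support interloper
    attached inside the family clade at support 60.  Two outgroup taxa root
    the tree.  Returns the alignment, loci, newick tree, anchor names and
    the expected outcome of the full filter chain.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA))
    base = rng.choice(aa, size=length)

    def mutate(seq: np.ndarray, n_sites: int) -> np.ndarray:
        out = seq.copy()
        sites = rng.choice(length, size=n_sites, replace=False)
        for s in sites:
            out[s] = rng.choice([c for c in _AA if c != out[s]])
        return out

    names = [f"fam{i:02d}" for i in range(1, n_distinct + 1)]
    rows = {name: mutate(base, int(0.08 * length)) for name in names}
    # planted alleles: < 2% difference, scattered across the sequence
    for parent in names[:2]:
        allele = rows[parent].copy()
        for s in (5, length - 6):
            allele[s] = rng.choice([c for c in _AA if c != allele[s]])
        rows[f"{parent}_allele"] = allele
    rows["interloper"] = mutate(base, int(0.35 * length))
    rows["outgroup1"] = mutate(base, int(0.45 * length))
    rows["outgroup2"] = mutate(base, int(0.45 * length))
    alignment = Alignment({k: "".join(v) for k, v in rows.items()})

    loci: dict[str, tuple[str, int, int, str]] = {}
    for i, name in enumerate(names):
        loci[name] = ("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 3_000, "+")
    # planted overlap: the last distinct gene intrudes into its neighbour
    prev_start = 10_000 * (n_distinct - 1)
    loci[names[-1]] = ("chr1", prev_start + 1_000, prev_start + 4_000, "+")
    loci[f"{names[0]}_allele"] = ("chr1", 900_000, 903_000, "+")
    loci[f"{names[1]}_allele"] = ("chr1", 910_000, 913_000, "+")
    loci["interloper"] = ("chr2", 5_000, 8_000, "+")

    half = n_distinct // 2
    clade_a = ",".join(names[:half] + [f"{names[0]}_allele", f"{names[1]}_allele"])
    clade_b = ",".join(names[half:])
    newick = (
        f"(outgroup1,outgroup2,(({clade_a})90,(({clade_b})90,interloper)60)95);"
    )
    anchors = [names[0], names[half]]
    candidates = [n for n in alignment if not n.startswith("outgroup")]
    expected_accepted = sorted(names[: n_distinct - 2])
    return {
        "alignment": alignment,
        "loci": loci,
        "newick": newick,
        "anchors": anchors,
        "candidates": candidates,
        "expected_accepted": expected_accepted,
        "expected_allele_pairs": [
            (names[0], f"{names[0]}_allele"),
            (names[1], f"{names[1]}_allele"),
        ],
        "expected_overlap_pair": (names[-2], names[-1]),
        "expected_unresolved": ["interloper"],
    }
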