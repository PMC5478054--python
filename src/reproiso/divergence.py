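"""Uncorrected sequence divergence and haplotype networks.

Distances are uncorrected p-distances with pairwise deletion: a site enters
the comparison only when both sequences carry an unambiguous base (A, C, G or
T); N and gap columns are excluded per pair, not alignment-wide.  Group
divergence is the arithmetic mean of all between-group pairwise percent
distances.

Identical sequences (zero mismatches over their comparable sites) are
collapsed into haplotypes, and a haplotype network is built as a minimum
spanning tree over the haplotypes with edge weight equal to the number of
differing comparable sites ("mutational steps").  An optional connection
limit removes edges above a step threshold afterwards, which may split the
network into components — the analogue of a statistical-parsimony connection
limit, whose numeric value is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import AlignmentError, AlignmentSet

__all__ = [
    "DistanceMatrix",
    "Haplotype",
    "HaplotypeNetwork",
    "pairwise_p_distance",
    "hamming_steps",
    "group_divergence_matrix",
    "collapse_haplotypes",
    "build_network",
]

_BASES = frozenset(b"ACGT")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def _comparable_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return np.isin(a, bases) & np.isin(b, bases)


def pairwise_p_distance(a: str, b: str) -> tuple[float, int]:
    """Percent p-distance and the number of comparable sites for one pair.

    Returns ``(nan, 0)`` when no site is comparable.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    ea, eb = _encode(a.upper()), _encode(b.upper())
    mask = _comparable_mask(ea, eb)
    comparable = int(mask.sum())
    if comparable == 0:
        return float("nan"), 0
    mismatches = int((ea[mask] != eb[mask]).sum())
    return 100.0 * mismatches / comparable, comparable


def hamming_steps(a: str, b: str) -> int:
    """Number of differing comparable sites (mutational steps) for one pair."""
    if len(a) != len(b):
        raise AlignmentError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    ea, eb = _encode(a.upper()), _encode(b.upper())
    mask = _comparable_mask(ea, eb)
    return int((ea[mask] != eb[mask]).sum())


@dataclass
class DistanceMatrix:
    """Square percent-divergence matrix with per-cell comparable-site counts."""

    labels: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def group_divergence_matrix(aln: AlignmentSet) -> DistanceMatrix:
    """Average percent divergence between groups of an alignment.

    Each between-group cell is the arithmetic mean of all inter-group
    pairwise percent distances; the diagonal is 0 by convention (within-group
    polymorphism is not averaged into it).  Comparable-site counts are
    averaged the same way.
    """
    groups = aln.groups
    members = {g: [r for r in aln.records if r.group == g] for g in groups}
    k = len(groups)
    values = np.zeros((k, k))
    sites = np.zeros((k, k))
    for i, gi in enumerate(groups):
        for j in range(i + 1, k):
            gj = groups[j]
            dists = []
            comps = []
            for ri in members[gi]:
                for rj in members[gj]:
                    d, c = pairwise_p_distance(ri.sequence, rj.sequence)
                    if c == 0:
                        raise AlignmentError(
                            f"no comparable sites between {ri.id!r} and {rj.id!r}"
                        )
                    dists.append(d)
                    comps.append(c)
            values[i, j] = values[j, i] = float(np.mean(dists))
            sites[i, j] = sites[j, i] = float(np.mean(comps))
    # diagonal comparable-site count: the alignment length is the natural cap
    np.fill_diagonal(sites, aln.length)
    return DistanceMatrix(labels=list(groups), values=values, comparable_sites=sites)


@dataclass
class Haplotype:
    id: str
    sequence: str
    members: list[str] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    nodes: list[Haplotype]
    edges: list[tuple[str, str, int]]
    connection_limit: int | None = None

    def edge_steps(self) -> dict[frozenset[str], int]:
        return {frozenset((u, v)): s for u, v, s in self.edges}

    @property
    def total_steps(self) -> int:
        return sum(s for _, _, s in self.edges)


def _n_count(seq: str) -> int:
    return seq.count("N")


def collapse_haplotypes(aln: AlignmentSet) -> list[Haplotype]:
    """Merge records that show zero mismatches over their comparable sites.

    Records join the first existing haplotype whose representative they match
    exactly (pairwise deletion), so a record differing only at an N site
    merges.  The representative is the member sequence with the fewest N
    characters (ties broken by lexicographic record id); haplotype ids are
    H1..Hk in order of first appearance.
    """
    haps: list[Haplotype] = []
    reps: list[tuple[str, str]] = []  # (record id, sequence) per haplotype
    by_id = {r.id: r.sequence for r in aln.records}
    for record in aln.records:
        for idx, hap in enumerate(haps):
            if hamming_steps(record.sequence, reps[idx][1]) == 0:
                hap.members.append(record.id)
                best = min(
                    hap.members, key=lambda rid: (_n_count(by_id[rid]), rid)
                )
                reps[idx] = (best, by_id[best])
                hap.sequence = by_id[best]
                break
        else:
            haps.append(
                Haplotype(id=f"H{len(haps) + 1}", sequence=record.sequence,
                          members=[record.id])
            )
            reps.append((record.id, record.sequence))
    return haps


def build_network(
    haps: list[Haplotype], connection_limit: int | None = None
) -> HaplotypeNetwork:
    """Minimum-spanning-tree haplotype network.

    Edge weight is the number of differing comparable sites between haplotype
    representatives.  Candidate edges are considered in (steps, id, id) order
    so ties break deterministically.  Edges whose step count exceeds
    ``connection_limit`` are removed after the tree is built, which may leave
    a forest.
    """
    if not haps:
        raise ValueError("need at least one haplotype")
    graph = nx.Graph()
    for hap in haps:
        graph.add_node(hap.id)
    candidates = []
    for i, hi in enumerate(haps):
        for hj in haps[i + 1:]:
            steps = hamming_steps(hi.sequence, hj.sequence)
            u, v = sorted((hi.id, hj.id))
            candidates.append((steps, u, v))
    # insertion order is the kruskal tie-break in networkx
    for steps, u, v in sorted(candidates):
        graph.add_edge(u, v, weight=steps)
    mst = nx.minimum_spanning_tree(graph, algorithm="kruskal")
    edges = sorted(
        (min(u, v), max(u, v), int(d["weight"]))
        for u, v, d in mst.edges(data=True)
    )
    if connection_limit is not None:
        edges = [e for e in edges if e[2] <= connection_limit]
    return HaplotypeNetwork(nodes=list(haps), edges=edges,
                            connection_limit=connection_limit)
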