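"""Gene-interaction network, truncated graph distances, and circular scan windows.

The network is an undirected graph whose nodes are genes (or their products)
and whose edges are interactions.  Distance between two genes is the shortest
path length in hops.  A *window* is the ball of genes within a given radius of
a center gene; scanning all centers with radii 0..R yields (R+1)*N candidate
clusters, which is what makes the scan computationally feasible compared with
the 2^N unrestricted subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "PathwayGraph",
    "DistanceIndex",
    "Window",
    "load_edge_list",
    "truncated_distances",
    "enumerate_windows",
    "dedupe_windows",
    "coverage_fraction",
]

#: Default maximum window radius.  At radius 4 the windows of a large
#: interactome cover essentially all reachable gene pairs.
DEFAULT_MAX_RADIUS = 4


class PathwayGraph:
    """Undirected gene network with a stable gene ordering.

    Self-loops are dropped and duplicate/reversed edges collapse to a single
    undirected edge.  Gene identifiers are opaque case-sensitive strings.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 genes: Iterable[str] = ()) -> None:
        g = nx.Graph()
        g.add_nodes_from(genes)
        for a, b in edges:
            if a == b:
                g.add_node(a)  # isolated node retained, self-loop dropped
            else:
                g.add_edge(a, b)
        self._g = g
        self._genes = tuple(g.nodes())
        self._index = {gene: i for i, gene in enumerate(self._genes)}

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "PathwayGraph":
        return cls(g.edges(), g.nodes())

    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    @property
    def N(self) -> int:
        return len(self._genes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._g.edges()}

    def gene_index(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_networkx(self) -> nx.Graph:
        return self._g

    def __repr__(self) -> str:  # pragma: no cover
        return f"PathwayGraph(N={self.N}, edges={self.n_edges})"


@dataclass
class DistanceIndex:
    """Hop distances truncated at radius ``R``.

    ``dist[k]`` maps gene l to d(k, l) for every l with d(k, l) <= R; pairs in
    different components (or farther than R) are simply absent.
    """

    R: int
    dist: Mapping[str, Mapping[str, int]]

    def get(self, k: str, l: str) -> int | None:
        return self.dist.get(k, {}).get(l)

    def ball(self, center: str, radius: int) -> frozenset:
        if radius > self.R:
            raise ValueError(f"radius {radius} exceeds index truncation R={self.R}")
        return frozenset(l for l, d in self.dist[center].items() if d <= radius)


@dataclass(frozen=True, order=True)
class Window:
    """Circular scan window: all genes within ``radius`` hops of ``center``."""

    center: str
    radius: int
    members: frozenset = field(compare=False)

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("window center must be a member")

    @property
    def size(self) -> int:
        return len(self.members)

    def overlaps(self, other: "Window") -> bool:
        return not self.members.isdisjoint(other.members)


class EdgeListParseError(ValueError):
    pass


def load_edge_list(path, format: str | None = None) -> PathwayGraph:
    """Read a gene network from a 2-column TSV edge list or a SIF file.

    TSV lines are ``gene_a<TAB>gene_b``; lines starting with ``#`` and blank
    lines are ignored.  SIF lines are whitespace-delimited
    ``node relation node [node ...]`` — the relation is discarded and an edge
    is added from the source to each listed target.  Direction is discarded,
    duplicates collapse, self-loops are dropped (the node is kept).
    """
    path = str(path)
    if format is None:
        format = "sif" if path.lower().endswith(".sif") else "tsv"
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge list format: {format!r}")

    edges: list[tuple[str, str]] = []
    genes: list[str] = []
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_data_lines += 1
            if format == "tsv":
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) != 2:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                a, b = fields
                genes.extend((a, b))
                edges.append((a, b))
            else:  # sif
                fields = line.split()
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: SIF line needs >= 3 fields, got {len(fields)}")
                src = fields[0]
                genes.append(src)
                for tgt in fields[2:]:
                    genes.append(tgt)
                    edges.append((src, tgt))
    if n_data_lines == 0:
        raise EdgeListParseError(f"{path}: empty edge list")
    return PathwayGraph(edges, genes)


def truncated_distances(g: PathwayGraph, R: int = DEFAULT_MAX_RADIUS) -> DistanceIndex:
    """All-pairs shortest hop distances truncated at radius ``R``.

    Edges have unit weight, so breadth-first search from every gene gives the
    same distances a general shortest-path algorithm (Dijkstra) would.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    nxg = g.to_networkx()
    dist = {
        gene: dict(nx.single_source_shortest_path_length(nxg, gene, cutoff=R))
        for gene in g.genes
    }
    return DistanceIndex(R=R, dist=dist)


def enumerate_windows(g: PathwayGraph, d: DistanceIndex,
                      R: int = DEFAULT_MAX_RADIUS) -> list[Window]:
    """All (R+1)*N circular windows, ordered by (center index, radius)."""
    if R > d.R:
        raise ValueError(f"distance index truncated at {d.R} < requested R={R}")
    windows: list[Window] = []
    for gene in g.genes:
        reach = d.dist[gene]
        for r in range(R + 1):
            members = frozenset(l for l, dd in reach.items() if dd <= r)
            windows.append(Window(center=gene, radius=r, members=members))
    return windows


def dedupe_windows(windows: Iterable[Window]) -> list[Window]:
    """Drop windows whose member set already appeared.

    The scan statistic is a function of the member set only, so removing
    duplicate member sets cannot change the scan maximum; the first
    (center-order, then radius) representative is kept.
    """
    seen: set[frozenset] = set()
    out: list[Window] = []
    for w in windows:
        if w.members not in seen:
            seen.add(w.members)
            out.append(w)
    return out


def coverage_fraction(g: PathwayGraph, diameter: int) -> float:
    """Fraction of unordered distinct gene pairs at shortest distance <= diameter.

    Unreachable pairs (different components) count in the denominator.  Used
    to justify the maximum radius R: windows of diameter 2R cover a pair iff
    the two genes are within 2R of each other.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    n = g.N
    if n < 2:
        return 1.0
    nxg = g.to_networkx()
    within = 0
    for gene in g.genes:
        reach = nx.single_source_shortest_path_length(nxg, gene, cutoff=diameter)
        within += len(reach) - 1  # exclude self
    return (within / 2) / (n * (n - 1) / 2)
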