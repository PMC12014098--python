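"""Lineage identification on the milestone graph.

Candidate lineages are simple paths whose endpoint milestones carry the
user-chosen start and end prevalent cell states. Pseudotime is the geodesic
(edge-weighted shortest-path) distance from a user-chosen origin milestone;
cells inherit the pseudotime of the milestone they are assigned to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx

from .errors import EmptyRegionError, ParameterError
from .io import MilestoneAnnotation, TrajectoryGraph

#: Pseudotime sentinel for milestones not connected to the origin.
UNREACHABLE = math.inf


def to_networkx(traj: TrajectoryGraph) -> nx.Graph:
    """Undirected weighted graph over milestones (isolated ones included)."""
    g = nx.Graph()
    g.add_nodes_from(traj.coordinates)
    for a, b, w in traj.edges:
        g.add_edge(a, b, weight=w)
    return g


@dataclass
class LineagePath:
    """An ordered, simple milestone walk from a start state to an end state."""

    milestone_sequence: list[str]
    start_state: str
    end_state: str
    total_weight: float

    @property
    def length(self) -> int:
        return len(self.milestone_sequence) - 1

    def to_dict(self) -> dict:
        return {
            "milestones": list(self.milestone_sequence),
            "start_state": self.start_state,
            "end_state": self.end_state,
            "length": self.length,
            "total_weight": self.total_weight,
        }


@dataclass
class PathSearchResult:
    """Sorted list of candidate paths plus a truncation flag."""

    paths: list[LineagePath]
    truncated: bool = False

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def __getitem__(self, i):
        return self.paths[i]


@dataclass
class CellRegion:
    """A named set of cells with a record of how it was selected."""

    region_id: str
    cell_ids: set[str]
    provenance: str = ""


@dataclass
class PseudotimeMap:
    """Geodesic distance from an origin milestone, inherited by cells."""

    origin_milestone: str
    values: dict[str, float]  # milestone -> distance; UNREACHABLE if disconnected
    cell_values: dict[str, float] = field(default_factory=dict)

    def is_reachable(self, milestone: str) -> bool:
        return self.values.get(milestone, UNREACHABLE) != UNREACHABLE


def connected_regions(traj: TrajectoryGraph) -> list[set[str]]:
    """Connected components of the milestone graph, largest-first then by
    smallest member for determinism."""
    comps = [set(c) for c in nx.connected_components(to_networkx(traj))]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def count_possible_transitions(states: set[str] | list[str]) -> int:
    """Number of ordered pairs of distinct cell states (A->B and B->A count
    separately), i.e. 2 * C(n, 2) = n(n-1)."""
    n = len(set(states))
    return n * (n - 1)


def enumerate_paths(
    traj: TrajectoryGraph,
    annotations: list[MilestoneAnnotation],
    start_state: str,
    end_state: str,
    max_length: int = 10,
    max_paths: int = 100,
) -> PathSearchResult:
    """All simple milestone paths from a start-state milestone to an
    end-state milestone, up to ``max_length`` edges.

    Paths are sorted by (edge count, total weight, milestone sequence) and
    the list is cut at ``max_paths`` with ``truncated`` set.
    """
    if max_length < 1:
        raise ParameterError(f"max_length must be >= 1, got {max_length}")
    if max_paths < 1:
        raise ParameterError(f"max_paths must be >= 1, got {max_paths}")

    state_of = {a.milestone_id: a.prevalent_state for a in annotations}
    sources = sorted(m for m, s in state_of.items() if s == start_state)
    targets = {m for m, s in state_of.items() if s == end_state}
    if not sources or not targets:
        return PathSearchResult(paths=[], truncated=False)

    g = to_networkx(traj)
    found: list[LineagePath] = []
    for src in sources:
        usable_targets = targets - {src}
        if not usable_targets:
            continue
        for seq in nx.all_simple_paths(g, src, usable_targets, cutoff=max_length):
            w = sum(g[a][b]["weight"] for a, b in zip(seq, seq[1:]))
            found.append(
                LineagePath(
                    milestone_sequence=list(seq),
                    start_state=start_state,
                    end_state=end_state,
                    total_weight=w,
                )
            )
    found.sort(key=lambda p: (p.length, p.total_weight, p.milestone_sequence))
    truncated = len(found) > max_paths
    return PathSearchResult(paths=found[:max_paths], truncated=truncated)


def select_region(
    traj: TrajectoryGraph,
    path: LineagePath,
    n_neighbors: int = 0,
    milestone_subset: list[str] | None = None,
    region_id: str = "region",
) -> CellRegion:
    """Cells assigned to chosen path milestones, dilated by ``n_neighbors``
    graph hops.

    ``milestone_subset`` restricts the seed milestones (must lie on the
    path); the default seeds are the whole path.
    """
    if n_neighbors < 0:
        raise ParameterError(f"n_neighbors must be >= 0, got {n_neighbors}")
    seeds = list(path.milestone_sequence)
    if milestone_subset is not None:
        bad = sorted(set(milestone_subset) - set(path.milestone_sequence))
        if bad:
            raise ParameterError(f"milestones not on the path: {bad}")
        seeds = list(milestone_subset)

    g = to_networkx(traj)
    chosen: set[str] = set()
    for seed in seeds:
        chosen.update(nx.single_source_shortest_path_length(g, seed, cutoff=n_neighbors))
    cell_ids = {c for c, m in traj.assignment.items() if m in chosen}
    if not cell_ids:
        raise EmptyRegionError(
            f"no cells assigned to milestones {sorted(chosen)} "
            f"(seeds {seeds}, n_neighbors={n_neighbors})"
        )
    provenance = (
        f"seeds={sorted(seeds)} n_neighbors={n_neighbors} "
        f"milestones={sorted(chosen)}"
    )
    return CellRegion(region_id=region_id, cell_ids=cell_ids, provenance=provenance)


def compute_pseudotime(traj: TrajectoryGraph, origin_milestone: str) -> PseudotimeMap:
    """Single-source shortest-path distances from the origin milestone,
    under edge weights; disconnected milestones get the UNREACHABLE
    sentinel (``inf``)."""
    if origin_milestone not in traj.coordinates:
        raise ParameterError(f"unknown origin milestone {origin_milestone!r}")
    g = to_networkx(traj)
    dist = nx.single_source_dijkstra_path_length(g, origin_milestone, weight="weight")
    values = {m: dist.get(m, UNREACHABLE) for m in traj.coordinates}
    cell_values = {c: values[m] for c, m in traj.assignment.items()}
    return PseudotimeMap(
        origin_milestone=origin_milestone, values=values, cell_values=cell_values
    )
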