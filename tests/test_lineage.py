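"""Connected regions, path enumeration, region selection and pseudotime."""

import math

import numpy as np
import pandas as pd
import pytest

from evocell import (
    CellTable,
    MilestoneAnnotation,
    TrajectoryGraph,
    UNREACHABLE,
    compute_pseudotime,
    connected_regions,
    count_possible_transitions,
    enumerate_paths,
    select_region,
)
from evocell.errors import EmptyRegionError, ParameterError
from oracles import bellman_ford, dfs_simple_paths, flood_fill_components, hop_ball


def random_traj(rng, n_nodes=8, p_edge=0.3, weighted=False, cells_per=2):
    nodes = [f"m{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = float(np.round(rng.uniform(0.1, 5.0), 3)) if weighted else 1.0
                edges.append((nodes[i], nodes[j], w))
    assignment = {}
    k = 0
    for m in nodes:
        for _ in range(cells_per):
            assignment[f"c{k}"] = m
            k += 1
    return TrajectoryGraph(
        coordinates={m: (float(i), 0.0) for i, m in enumerate(nodes)},
        edges=edges,
        assignment=assignment,
    )


def chain_traj(states=("G1S", "S", "G0"), cells_per=2):
    nodes = [f"m{i + 1}" for i in range(len(states))]
    assignment = {}
    cell_state = {}
    k = 0
    for m, s in zip(nodes, states):
        for _ in range(cells_per):
            cid = f"c{k}"
            assignment[cid] = m
            cell_state[cid] = s
            k += 1
    traj = TrajectoryGraph(
        coordinates={m: (float(i), 0.0) for i, m in enumerate(nodes)},
        edges=[(nodes[i], nodes[i + 1], 1.0) for i in range(len(nodes) - 1)],
        assignment=assignment,
    )
    annotations = [
        MilestoneAnnotation(m, s, {s: cells_per}) for m, s in zip(nodes, states)
    ]
    return traj, annotations


class TestConnectedRegions:
    def test_two_disjoint_chains(self):
        traj = TrajectoryGraph(
            coordinates={f"m{i}": (float(i), 0.0) for i in range(6)},
            edges=[("m0", "m1", 1), ("m1", "m2", 1), ("m3", "m4", 1), ("m4", "m5", 1)],
            assignment={},
        )
        comps = connected_regions(traj)
        assert sorted(map(len, comps)) == [3, 3]

    def test_matches_flood_fill_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            traj = random_traj(rng, n_nodes=int(rng.integers(2, 12)))
            got = {frozenset(c) for c in connected_regions(traj)}
            want = {
                frozenset(c)
                for c in flood_fill_components(
                    traj.milestones, [(a, b) for a, b, _ in traj.edges]
                )
            }
            assert got == want


class TestCountPossibleTransitions:
    @pytest.mark.parametrize("n,expected", [(30, 870), (2, 2), (1, 0)])
    def test_ordered_pairs_of_distinct_states(self, n, expected):
        assert count_possible_transitions({f"s{i}" for i in range(n)}) == expected


class TestEnumeratePaths:
    def test_unique_path_on_labeled_chain(self):
        traj, ann = chain_traj()
        result = enumerate_paths(traj, ann, "G1S", "G0")
        assert [p.milestone_sequence for p in result] == [["m1", "m2", "m3"]]
        assert result[0].length == 2 and result[0].total_weight == 2.0

    def test_direction_matters(self):
        traj, ann = chain_traj()
        result = enumerate_paths(traj, ann, "G0", "G1S")
        assert [p.milestone_sequence for p in result] == [["m3", "m2", "m1"]]

    def test_absent_state_gives_empty_result(self):
        traj, ann = chain_traj()
        assert len(enumerate_paths(traj, ann, "G1S", "NOPE")) == 0

    def test_invalid_budgets_rejected(self):
        traj, ann = chain_traj()
        with pytest.raises(ParameterError):
            enumerate_paths(traj, ann, "G1S", "G0", max_length=0)
        with pytest.raises(ParameterError):
            enumerate_paths(traj, ann, "G1S", "G0", max_paths=0)

    def test_matches_exhaustive_dfs_on_random_labeled_graphs(self):
        rng = np.random.default_rng(7)
        states = ["A", "B", "C"]
        for _ in range(50):
            n = int(rng.integers(3, 11))
            traj = random_traj(rng, n_nodes=n, p_edge=0.35)
            labels = {m: states[int(rng.integers(0, 3))] for m in traj.milestones}
            ann = [MilestoneAnnotation(m, labels[m], {}) for m in traj.milestones]
            max_len = int(rng.integers(1, n + 1))
            result = enumerate_paths(traj, ann, "A", "B",
                                     max_length=max_len, max_paths=100000)
            got = sorted(p.milestone_sequence for p in result)
            sources = {m for m in traj.milestones if labels[m] == "A"}
            targets = {m for m in traj.milestones if labels[m] == "B"}
            want = sorted(
                p for p in dfs_simple_paths(
                    traj.milestones, [(a, b) for a, b, _ in traj.edges],
                    sources, targets, max_len)
                if labels[p[-1]] == "B"
            )
            assert got == want

    def test_monotone_in_length_budget(self):
        rng = np.random.default_rng(3)
        traj = random_traj(rng, n_nodes=8, p_edge=0.4)
        labels = {m: ("A" if i % 2 else "B") for i, m in enumerate(traj.milestones)}
        ann = [MilestoneAnnotation(m, labels[m], {}) for m in traj.milestones]
        for L in range(1, 7):
            small = {tuple(p.milestone_sequence)
                     for p in enumerate_paths(traj, ann, "A", "B", L, 100000)}
            large = {tuple(p.milestone_sequence)
                     for p in enumerate_paths(traj, ann, "A", "B", L + 1, 100000)}
            assert small <= large

    def test_truncation_flag(self):
        rng = np.random.default_rng(9)
        traj = random_traj(rng, n_nodes=8, p_edge=0.8)
        labels = {m: ("A" if i < 4 else "B") for i, m in enumerate(traj.milestones)}
        ann = [MilestoneAnnotation(m, labels[m], {}) for m in traj.milestones]
        full = enumerate_paths(traj, ann, "A", "B", max_length=8, max_paths=100000)
        cut = enumerate_paths(traj, ann, "A", "B", max_length=8, max_paths=3)
        assert len(full) > 3
        assert len(cut) == 3 and cut.truncated

    def test_invariant_under_milestone_relabeling(self):
        rng = np.random.default_rng(5)
        traj = random_traj(rng, n_nodes=6, p_edge=0.5)
        labels = {m: ("A" if i % 2 else "B") for i, m in enumerate(traj.milestones)}
        ann = [MilestoneAnnotation(m, labels[m], {}) for m in traj.milestones]
        base = enumerate_paths(traj, ann, "A", "B", 6, 100000)
        rename = {m: f"x{9 - i}" for i, m in enumerate(traj.milestones)}
        traj2 = TrajectoryGraph(
            coordinates={rename[m]: xy for m, xy in traj.coordinates.items()},
            edges=[(rename[a], rename[b], w) for a, b, w in traj.edges],
            assignment={c: rename[m] for c, m in traj.assignment.items()},
        )
        ann2 = [MilestoneAnnotation(rename[a.milestone_id], a.prevalent_state, {})
                for a in ann]
        renamed = enumerate_paths(traj2, ann2, "A", "B", 6, 100000)
        got = {tuple(p.milestone_sequence) for p in renamed}
        want = {tuple(rename[m] for m in p.milestone_sequence) for p in base}
        assert got == want


class TestSelectRegion:
    def test_radius_zero_is_own_cells(self):
        traj, ann = chain_traj(cells_per=5)
        path = enumerate_paths(traj, ann, "G1S", "G0")[0]
        region = select_region(traj, path, n_neighbors=0, milestone_subset=["m2"])
        assert region.cell_ids == set(traj.cells_of("m2"))
        assert len(region.cell_ids) == 5

    def test_unit_ball_on_chain(self):
        traj, ann = chain_traj()
        path = enumerate_paths(traj, ann, "G1S", "G0")[0]
        region = select_region(traj, path, n_neighbors=1, milestone_subset=["m2"])
        assert region.cell_ids == set(traj.assignment)

    def test_matches_bfs_ball_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            traj = random_traj(rng, n_nodes=int(rng.integers(3, 10)), p_edge=0.4)
            labels = {m: "A" for m in traj.milestones}
            ann = [MilestoneAnnotation(m, labels[m], {}) for m in traj.milestones]
            result = enumerate_paths(traj, ann, "A", "A", 8, 100000)
            if not result.paths:
                continue
            path = result[0]
            radius = int(rng.integers(0, 4))
            region = select_region(traj, path, n_neighbors=radius)
            ball = hop_ball(traj.milestones, [(a, b) for a, b, _ in traj.edges],
                            set(path.milestone_sequence), radius)
            want = {c for c, m in traj.assignment.items() if m in ball}
            assert region.cell_ids == want

    def test_monotone_in_radius(self):
        traj, ann = chain_traj()
        path = enumerate_paths(traj, ann, "G1S", "G0")[0]
        prev = set()
        for r in range(3):
            cur = select_region(traj, path, n_neighbors=r,
                                milestone_subset=["m1"]).cell_ids
            assert prev <= cur
            prev = cur

    def test_empty_region_is_error(self):
        traj, ann = chain_traj()
        traj2 = TrajectoryGraph(coordinates=traj.coordinates, edges=traj.edges,
                                assignment={})
        path = enumerate_paths(traj, ann, "G1S", "G0")[0]
        with pytest.raises(EmptyRegionError):
            select_region(traj2, path, n_neighbors=0)


class TestPseudotime:
    def test_unit_chain_distances(self):
        traj, _ = chain_traj()
        pt = compute_pseudotime(traj, "m1")
        assert pt.values == {"m1": 0.0, "m2": 1.0, "m3": 2.0}
        assert pt.cell_values["c0"] == 0.0

    def test_disconnected_gets_unreachable_sentinel(self):
        traj = TrajectoryGraph(
            coordinates={"m1": (0, 0), "m2": (1, 0), "m3": (9, 9)},
            edges=[("m1", "m2", 1.0)],
            assignment={},
        )
        pt = compute_pseudotime(traj, "m1")
        assert pt.values["m3"] == UNREACHABLE
        assert not pt.is_reachable("m3")

    def test_unknown_origin_rejected(self):
        traj, _ = chain_traj()
        with pytest.raises(ParameterError):
            compute_pseudotime(traj, "nope")

    def test_matches_bellman_ford_on_random_weighted_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            traj = random_traj(rng, n_nodes=int(rng.integers(2, 10)),
                               p_edge=0.4, weighted=True)
            origin = traj.milestones[int(rng.integers(0, len(traj.milestones)))]
            pt = compute_pseudotime(traj, origin)
            want = bellman_ford(traj.milestones, traj.edges, origin)
            for m in traj.milestones:
                assert pt.values[m] == pytest.approx(want[m])

    def test_triangle_inequality_along_edges(self):
        rng = np.random.default_rng(17)
        traj = random_traj(rng, n_nodes=9, p_edge=0.4, weighted=True)
        origin = traj.milestones[0]
        pt = compute_pseudotime(traj, origin)
        for a, b, w in traj.edges:
            if pt.is_reachable(a) and pt.is_reachable(b):
                assert abs(pt.values[a] - pt.values[b]) <= w + 1e-12
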