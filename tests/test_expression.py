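"""DGE methods, BH adjustment, terminal states and driver-gene ranking."""

import numpy as np
import pandas as pd
import pytest

from evocell import (
    CellRegion,
    CountMatrix,
    MilestoneAnnotation,
    TrajectoryGraph,
    SyntheticSpec,
    bh_adjust,
    compute_pseudotime,
    differential_expression,
    find_terminal_states,
    make_trajectory,
    normalize_counts,
    rank_driver_genes,
    simulate_counts,
)
from evocell.errors import DataValueError, ParameterError
from evocell.expression import spearman_vs_pseudotime, _wilcoxon_p
from evocell.lineage import PseudotimeMap
from oracles import bh_stepup


def small_counts(values, n_genes=None):
    values = np.asarray(values)
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(genes=genes, cells=cells, values=values)


class TestNormalize:
    def test_single_cell_closed_form(self):
        counts = small_counts([[1], [1], [2]])
        out = normalize_counts(counts)
        want = np.log1p(np.array([[250000.0], [250000.0], [500000.0]]))
        assert np.allclose(out, want)

    def test_cpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = small_counts(rng.integers(0, 20, size=(30, 10)) + 1)
        from evocell.expression import cpm

        assert np.allclose(cpm(counts).sum(axis=0), 1e6)

    def test_zero_library_cell_is_error(self):
        counts = small_counts([[1, 0], [2, 0]])
        with pytest.raises(DataValueError, match="c1"):
            normalize_counts(counts)

    def test_identical_columns_stay_identical(self):
        counts = small_counts(np.tile([[3], [1], [7]], (1, 4)))
        out = normalize_counts(counts)
        assert np.allclose(out, out[:, :1])


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_stepup(list(p)), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 200)
        assert np.all(bh_adjust(p) >= p - 1e-15)


def _two_regions(n=6):
    a = CellRegion("A", {f"c{j}" for j in range(n // 2)})
    b = CellRegion("B", {f"c{j}" for j in range(n // 2, n)})
    return a, b


class TestDifferentialExpression:
    def test_identical_vectors_are_null(self):
        block = np.array([[5, 1, 3], [2, 2, 2], [0, 7, 1]])
        counts = small_counts(np.hstack([block, block]))
        a, b = _two_regions()
        results = differential_expression(counts, a, b, method="wilcoxon",
                                          min_cells_expressing=1)
        for r in results:
            assert r.log2fc == pytest.approx(0.0)
            assert r.p_value == pytest.approx(1.0)

    def test_overlapping_regions_rejected(self, dge_bundle):
        a = dge_bundle["region_a"]
        bad = CellRegion("B", set(list(a.cell_ids)[:5]) | {"other"})
        with pytest.raises(ParameterError, match="overlap"):
            differential_expression(dge_bundle["counts"], a, bad)

    def test_tiny_region_rejected(self, dge_bundle):
        a = CellRegion("A", set(list(dge_bundle["region_a"].cell_ids)[:2]))
        with pytest.raises(ParameterError, match=">= 3"):
            differential_expression(dge_bundle["counts"], a, dge_bundle["region_b"])

    def test_expression_filter_removes_untested_genes(self, dge_bundle):
        counts = dge_bundle["counts"]
        silenced = counts.values.copy()
        silenced[7, :] = 0
        counts2 = CountMatrix(counts.genes, counts.cells, silenced)
        results = differential_expression(counts2, dge_bundle["region_a"],
                                          dge_bundle["region_b"])
        assert counts.genes[7] not in {r.gene for r in results}

    @pytest.mark.parametrize("method", ["wilcoxon", "nb_wald"])
    def test_swapping_regions_negates_log2fc_keeps_p(self, dge_bundle, method):
        kw = dict(method=method, min_cells_expressing=3)
        fwd = differential_expression(dge_bundle["counts"], dge_bundle["region_a"],
                                      dge_bundle["region_b"], **kw)
        rev = differential_expression(dge_bundle["counts"], dge_bundle["region_b"],
                                      dge_bundle["region_a"], **kw)
        rev_by_gene = {r.gene: r for r in rev}
        for r in fwd:
            s = rev_by_gene[r.gene]
            assert r.log2fc == pytest.approx(-s.log2fc, abs=1e-9)
            assert r.p_value == pytest.approx(s.p_value, rel=1e-6)

    @pytest.mark.parametrize("method", ["wilcoxon", "nb_wald"])
    def test_planted_fourfold_genes_recovered(self, dge_bundle, method):
        results = differential_expression(dge_bundle["counts"], dge_bundle["region_a"],
                                          dge_bundle["region_b"], method=method)
        hits = {r.gene for r in results if r.p_adjusted < 0.05 and r.log2fc > 0}
        truth = dge_bundle["truth"].de_genes
        assert len(hits & truth) >= 18  # >= 90% of the 20 planted genes

    def test_wilcoxon_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.gamma(2, 1, size=(20, 15))
        b = rng.gamma(2, 1.5, size=(20, 12))
        base = _wilcoxon_p(a, b)
        warped = _wilcoxon_p(np.exp(a), np.exp(b))
        assert np.allclose(base, warped)


class TestTerminalStates:
    def _annotations(self, traj):
        return [MilestoneAnnotation(m, f"state_{m}", {}) for m in traj.milestones]

    def test_chain_endpoint_terminal(self):
        traj = TrajectoryGraph(
            coordinates={"m1": (0, 0), "m2": (1, 0), "m3": (2, 0)},
            edges=[("m1", "m2", 1.0), ("m2", "m3", 1.0)],
            assignment={},
        )
        report = find_terminal_states(traj, compute_pseudotime(traj, "m1"),
                                      self._annotations(traj))
        assert report.terminal_milestones == ["m3"]
        assert report.terminal_states == ["state_m3"]

    def test_star_hub_origin_all_leaves_terminal(self):
        nodes = ["hub"] + [f"l{i}" for i in range(4)]
        traj = TrajectoryGraph(
            coordinates={m: (float(i), 0.0) for i, m in enumerate(nodes)},
            edges=[("hub", f"l{i}", 1.0) for i in range(4)],
            assignment={},
        )
        report = find_terminal_states(traj, compute_pseudotime(traj, "hub"),
                                      self._annotations(traj))
        assert sorted(report.terminal_milestones) == [f"l{i}" for i in range(4)]
        assert "hub" not in report.terminal_milestones

    def test_isolated_origin_is_terminal(self):
        traj = TrajectoryGraph(coordinates={"m1": (0, 0)}, edges=[], assignment={})
        report = find_terminal_states(traj, compute_pseudotime(traj, "m1"),
                                      self._annotations(traj))
        assert report.terminal_milestones == ["m1"]

    def test_random_trees_match_local_maximum_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            nodes = [f"m{i}" for i in range(n)]
            edges = [(nodes[int(rng.integers(0, i))], nodes[i],
                      float(np.round(rng.uniform(0.5, 3.0), 2)))
                     for i in range(1, n)]
            traj = TrajectoryGraph(
                coordinates={m: (float(i), 0.0) for i, m in enumerate(nodes)},
                edges=edges, assignment={},
            )
            pt = compute_pseudotime(traj, "m0")
            report = find_terminal_states(traj, pt, self._annotations(traj))
            neighbors = {m: set() for m in nodes}
            for a, b, _ in edges:
                neighbors[a].add(b)
                neighbors[b].add(a)
            want = [
                m for m in sorted(nodes)
                if all(pt.values[nb] <= pt.values[m] for nb in neighbors[m])
                and (m != "m0" or not neighbors[m])
            ]
            assert report.terminal_milestones == want


class TestDriverGenes:
    def _region_and_pt(self, counts, n):
        region = CellRegion("R", set(counts.cells))
        pt = PseudotimeMap(
            origin_milestone="m0",
            values={},
            cell_values={c: float(i) for i, c in enumerate(counts.cells)},
        )
        return region, pt

    def test_perfect_monotone_gene(self):
        n = 12
        base = np.ones((3, n), dtype=int) * 50
        base[0] = 10 * (np.arange(n) + 1)  # strictly increasing with pt order
        counts = small_counts(base)
        region, pt = self._region_and_pt(counts, n)
        results = rank_driver_genes(counts, region, pt)
        top = results[0]
        assert top.gene == "G0"
        assert top.correlation == pytest.approx(1.0)
        assert top.direction == "up"

    def test_constant_pseudotime_rejected(self):
        counts = small_counts(np.ones((2, 12), dtype=int))
        region = CellRegion("R", set(counts.cells))
        pt = PseudotimeMap("m0", {}, {c: 1.0 for c in counts.cells})
        with pytest.raises(ParameterError, match="constant"):
            rank_driver_genes(counts, region, pt)

    def test_too_few_cells_rejected(self):
        counts = small_counts(np.ones((2, 5), dtype=int))
        region = CellRegion("R", set(counts.cells))
        pt = PseudotimeMap("m0", {}, {c: float(i) for i, c in enumerate(counts.cells)})
        with pytest.raises(ParameterError, match=">= 10"):
            rank_driver_genes(counts, region, pt)

    def test_spearman_matches_scipy_per_gene(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        expr = rng.gamma(2, 3, size=(15, 40))
        ptv = rng.uniform(0, 10, 40)
        r, p = spearman_vs_pseudotime(expr, ptv)
        for i in range(expr.shape[0]):
            want = stats.spearmanr(expr[i], ptv)
            assert r[i] == pytest.approx(want.statistic, abs=1e-10)
            assert p[i] == pytest.approx(want.pvalue, rel=1e-6)

    def test_planted_drivers_rank_at_top(self):
        spec = SyntheticSpec(seed=3, n_genes=200, n_de_genes=0, n_driver_genes=10)
        cells, traj, truth = make_trajectory(spec)
        pt = compute_pseudotime(traj, truth.root_milestone)
        counts, truth = simulate_counts(spec, cells, pt, truth)
        region = CellRegion("all", set(cells.cell_id))
        results = rank_driver_genes(counts, region, pt)
        top15 = {r.gene for r in results[:15]}
        assert truth.driver_genes <= top15

    def test_permuted_null_calibration(self):
        rng = np.random.default_rng(10)
        fracs = []
        for _ in range(20):
            expr = rng.gamma(2, 3, size=(200, 100))
            ptv = rng.uniform(0, 5, 100)
            _, p = spearman_vs_pseudotime(expr, ptv)
            fracs.append(np.mean(p < 0.05))
        assert abs(np.mean(fracs) - 0.05) <= 0.03
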