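"""Seeded synthetic datasets with planted ground truth.

Generates everything the pipeline consumes, offline: a milestone trajectory
of a chosen topology with state-labelled cells, a negative-binomial count
matrix with planted differentially expressed genes and pseudotime-monotone
driver genes, GMT gene-set collections with one planted set among random
decoys, a synthetic PubMed title store, and scripted mock-LLM responses at
three fidelity levels (faithful, noisy, adversarial).

Every generator is a pure function of its spec and seed. The negative
binomial is parameterized as variance = mu + dispersion * mu^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CellTable, CountMatrix, TrajectoryGraph, write_dataset
from .lineage import PseudotimeMap, compute_pseudotime
from .gsea import GeneSet, write_gmt

#: Cell-cycle-flavoured default state labels; beyond six, generic labels.
_STATE_NAMES = ["G1S", "S", "G0", "G2M", "QUIESCENT", "SENESCENT"]

#: log fold of the planted driver trend over the pseudotime range.
DRIVER_BETA = math.log(4.0)

_DECOY_VOCAB = [
    "mitochondrial", "proteomic", "zebrafish", "cardiac", "fibrosis",
    "autophagy", "kinome", "epigenetic", "microbiome", "organoid",
    "glioma", "retina", "hepatic", "splicing", "chromatin", "metabolite",
    "vaccine", "antibody", "receptor", "membrane", "cartilage", "neuron",
]

_FABRICATED_VOCAB = [
    "imaginary", "flux", "modulation", "hypothetical", "resonance",
    "quantum", "vortex", "synthetic", "paradigm", "holographic",
    "crystalline", "entropic", "fictive", "spectral", "axiomatic",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_states: int = 3
    topology: str = "chain"  # chain | branch | star | random_tree
    n_milestones: int = 6
    cells_per_milestone: int = 100
    n_genes: int = 500
    n_de_genes: int = 20
    de_fold: float = 4.0
    n_driver_genes: int = 10
    nb_dispersion: float = 0.1
    state_purity: float = 0.9

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "branch", "star", "random_tree"):
            raise ParameterError(f"unknown topology {self.topology!r}")
        for name in ("n_states", "n_milestones", "cells_per_milestone", "n_genes"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if self.n_de_genes < 0 or self.n_driver_genes < 0:
            raise ParameterError("gene counts must be nonnegative")
        if self.n_de_genes + self.n_driver_genes > self.n_genes:
            raise ParameterError("n_de_genes + n_driver_genes exceeds n_genes")
        if self.de_fold < 1:
            raise ParameterError("de_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if not 0.5 < self.state_purity <= 1.0:
            raise ParameterError("state_purity must be in (0.5, 1]")
        if self.n_states > self.n_milestones:
            raise ParameterError("need at least one milestone per state")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    states: list[str] = field(default_factory=list)
    root_milestone: str = ""
    designated_states: dict[str, str] = field(default_factory=dict)
    true_transitions: set[tuple[str, str]] = field(default_factory=set)
    terminal_milestones: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    driver_genes: set[str] = field(default_factory=set)
    de_region_cells: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "states": self.states,
            "root_milestone": self.root_milestone,
            "designated_states": self.designated_states,
            "true_transitions": sorted(list(t) for t in self.true_transitions),
            "terminal_milestones": sorted(self.terminal_milestones),
            "de_genes": sorted(self.de_genes),
            "driver_genes": sorted(self.driver_genes),
            "de_region_cells": sorted(self.de_region_cells),
        }


def state_names(n: int) -> list[str]:
    return [_STATE_NAMES[i] if i < len(_STATE_NAMES) else f"STATE{i:02d}" for i in range(n)]


def _topology_edges(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    k = spec.n_milestones
    if k == 1:
        return []
    if spec.topology == "chain":
        return [(i, i + 1) for i in range(k - 1)]
    if spec.topology == "star":
        return [(0, i) for i in range(1, k)]
    if spec.topology == "branch":
        trunk = max(1, k // 2)
        edges = [(i, i + 1) for i in range(trunk - 1)]
        arm_a, arm_b = trunk - 1, trunk - 1  # both arms grow from trunk end
        for i in range(trunk, k):
            if (i - trunk) % 2 == 0:
                edges.append((arm_a, i))
                arm_a = i
            else:
                edges.append((arm_b, i))
                arm_b = i
        return edges
    # random_tree: attach each new node to a uniformly chosen earlier node
    return [(int(rng.integers(0, i)), i) for i in range(1, k)]


def make_trajectory(spec: SyntheticSpec) -> tuple[CellTable, TrajectoryGraph, GroundTruth]:
    """Milestone graph of the requested topology with state-labelled cells.

    Milestones are labelled with designated states in contiguous blocks
    along a BFS order from the root; each milestone's cells carry its
    designated state with probability ``state_purity``, otherwise a state
    drawn uniformly from the remaining ones. True transitions are the
    designated-state pairs along edges oriented away from the root.
    """
    rng = np.random.default_rng([spec.seed, 1])
    k = spec.n_milestones
    ids = [f"m{i + 1:02d}" for i in range(k)]
    edges_idx = _topology_edges(spec, rng)

    # BFS order/depth from the root (node 0); edges list keeps parents first
    children: dict[int, list[int]] = {i: [] for i in range(k)}
    for a, b in edges_idx:
        children[a].append(b)
    depth = {0: 0}
    order = [0]
    for node in order:
        for ch in children[node]:
            depth[ch] = depth[node] + 1
            order.append(ch)

    states = state_names(spec.n_states)
    designated = {
        ids[node]: states[min(rank * spec.n_states // k, spec.n_states - 1)]
        for rank, node in enumerate(order)
    }

    per_depth: dict[int, int] = {}
    coordinates = {}
    for node in order:
        d = depth[node]
        coordinates[ids[node]] = (float(d), float(per_depth.get(d, 0)))
        per_depth[d] = per_depth.get(d, 0) + 1

    edges = [(ids[a], ids[b], 1.0) for a, b in edges_idx]

    cell_ids, cell_state, assignment, timepoints = [], {}, {}, []
    counter = 0
    for node in order:
        m = ids[node]
        for _ in range(spec.cells_per_milestone):
            cid = f"cell_{counter:05d}"
            counter += 1
            if rng.random() < spec.state_purity or spec.n_states == 1:
                st = designated[m]
            else:
                others = [s for s in states if s != designated[m]]
                st = others[int(rng.integers(0, len(others)))]
            cell_ids.append(cid)
            cell_state[cid] = st
            assignment[cid] = m
            timepoints.append(depth[node])

    covariates = pd.DataFrame({"timepoint": timepoints}, index=cell_ids)
    cells = CellTable(cell_id=cell_ids, cell_state=cell_state, covariates=covariates)
    traj = TrajectoryGraph(coordinates=coordinates, edges=edges, assignment=assignment)

    transitions = {
        (designated[ids[a]], designated[ids[b]])
        for a, b in edges_idx
        if designated[ids[a]] != designated[ids[b]]
    }
    leaves = {ids[i] for i in range(k) if not children[i] and i != 0} or {ids[0]}
    truth = GroundTruth(
        states=states,
        root_milestone=ids[0],
        designated_states=designated,
        true_transitions=transitions,
        terminal_milestones=leaves,
    )
    return cells, traj, truth


def simulate_counts(
    spec: SyntheticSpec,
    cells: CellTable,
    pt: PseudotimeMap,
    truth: GroundTruth | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts with planted DE and driver genes.

    Background genes are NB(mu_g, dispersion) i.i.d. per cell with
    mu_g ~ LogNormal(ln 5, 1). The first ``n_de_genes`` genes have mu
    multiplied by ``de_fold`` in the designated DE region (cells in the
    upper half of scaled pseudotime); the next ``n_driver_genes`` genes
    have mu scaled by exp(beta * pt_scaled) with beta = ln 4, a monotone
    pseudotime trend.
    """
    rng = np.random.default_rng([spec.seed, 2])
    truth = truth or GroundTruth()
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    n_cells = cells.n_cells

    pt_vals = np.asarray([pt.cell_values.get(c, math.inf) for c in cells.cell_id])
    finite = np.isfinite(pt_vals)
    max_pt = pt_vals[finite].max() if finite.any() else 0.0
    pt_scaled = np.where(finite, pt_vals / max_pt if max_pt > 0 else 0.0, 0.0)

    de_region = (pt_scaled >= 0.5) & finite
    if spec.n_de_genes > 0 and not de_region.any():
        raise ParameterError("no cells in the upper pseudotime half to plant DE genes")

    mu_g = rng.lognormal(mean=math.log(5.0), sigma=1.0, size=spec.n_genes)
    mu = np.repeat(mu_g[:, None], n_cells, axis=1)
    de_idx = np.arange(spec.n_de_genes)
    driver_idx = np.arange(spec.n_de_genes, spec.n_de_genes + spec.n_driver_genes)
    if de_idx.size:
        mu[np.ix_(de_idx, np.flatnonzero(de_region))] *= spec.de_fold
    if driver_idx.size:
        mu[driver_idx, :] *= np.exp(DRIVER_BETA * pt_scaled)[None, :]

    r = 1.0 / spec.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    values = rng.poisson(lam)

    counts = CountMatrix(genes=genes, cells=list(cells.cell_id), values=values)
    truth.de_genes = {genes[i] for i in de_idx}
    truth.driver_genes = {genes[i] for i in driver_idx}
    truth.de_region_cells = {
        c for c, inside in zip(cells.cell_id, de_region) if inside
    }
    return counts, truth


def make_gene_sets(
    truth: GroundTruth,
    all_genes: list[str],
    n_decoys: int = 20,
    decoy_size: int = 20,
    seed: int = 0,
) -> list[GeneSet]:
    """The planted DE set plus random same-size decoy sets."""
    rng = np.random.default_rng([seed, 3])
    sets = []
    if truth.de_genes:
        sets.append(GeneSet(name="PLANTED_DE_UP", members=set(truth.de_genes),
                            description="planted upregulated genes"))
    background = [g for g in all_genes if g not in truth.de_genes]
    for i in range(n_decoys):
        members = rng.choice(len(background), size=min(decoy_size, len(background)),
                             replace=False)
        sets.append(GeneSet(
            name=f"DECOY_{i + 1:02d}",
            members={background[j] for j in members},
            description="random decoy set",
        ))
    return sets


def _true_title(frm: str, to: str) -> str:
    return (
        f"Evidence that {frm} cells transition into {to} cells during "
        "lineage progression"
    )


def make_pubmed_fixture(
    truth: GroundTruth, n_decoys: int = 10, seed: int = 0
) -> list[dict]:
    """JSON-able PubMed store: one title per true transition plus decoys.

    Decoy titles draw from a vocabulary disjoint from the true-title
    template, and are screened so no decoy shares a 5-token run with any
    true title.
    """
    from .veracity import longest_consecutive_match, normalize_title

    rng = np.random.default_rng([seed, 4])
    records = []
    true_norms = []
    for i, (frm, to) in enumerate(sorted(truth.true_transitions)):
        title = _true_title(frm, to)
        records.append({"pmid": f"1{i:07d}", "title": title})
        true_norms.append(normalize_title(title))
    made = 0
    while made < n_decoys:
        words = rng.choice(len(_DECOY_VOCAB), size=8, replace=True)
        title = " ".join(_DECOY_VOCAB[w] for w in words).capitalize() + " in model systems"
        norm = normalize_title(title)
        if all(longest_consecutive_match(norm, t)[0] < 5 for t in true_norms):
            records.append({"pmid": f"2{made:07d}", "title": title})
            made += 1
    return records


def _fenced(lines: list[str]) -> str:
    return "```\n" + "\n".join(lines) + "\n```\n"


def _hypothesis_block(
    transitions: list[tuple[str, str]],
    titles_for: dict[tuple[str, str], list[str]] | None,
) -> str:
    lines = []
    for frm, to in transitions:
        lines.append(f"TRANSITION: {frm} -> {to}")
        lines.append(f"RATIONALE: {frm} cells are known to progress toward {to}.")
        if titles_for is not None:
            for title in titles_for[(frm, to)]:
                lines.append(f"TITLE: {title}")
    return _fenced(lines)


def _genuine_titles(frm: str, to: str) -> list[str]:
    base = _true_title(frm, to)
    return [base, f"New findings: {base}", f"{base}: a single cell study"]


def _fabricated_titles(rng: np.random.Generator) -> list[str]:
    out = []
    for _ in range(3):
        words = rng.choice(len(_FABRICATED_VOCAB), size=7, replace=True)
        out.append(" ".join(_FABRICATED_VOCAB[w] for w in words).capitalize())
    return out


def make_llm_script(
    truth: GroundTruth,
    fidelity: str = "faithful",
    seed: int = 0,
    n_variants: int = 10,
) -> list[dict]:
    """Scripted mock-provider rules at the requested fidelity.

    faithful: exactly the true transitions, three genuine titles each.
    noisy: per response variant, the true transitions (genuine titles)
    plus an equal number of spurious in-inventory transitions carrying
    fabricated titles. adversarial: malformed outputs for parser fuzzing.
    """
    if fidelity not in ("faithful", "noisy", "adversarial"):
        raise ParameterError(f"unknown fidelity {fidelity!r}")
    true_sorted = sorted(truth.true_transitions)
    titles = {t: _genuine_titles(*t) for t in true_sorted}

    if fidelity == "faithful":
        engineered = _hypothesis_block(true_sorted, titles)
        naive = _hypothesis_block(true_sorted, None)
        claim = _fenced(
            [f"TITLE: {_true_title(*true_sorted[0])}"] if true_sorted else ["TITLE: none"]
        )
        eng_resp: str | list = engineered
        naive_resp: str | list = naive
    elif fidelity == "noisy":
        all_pairs = [
            (a, b) for a in truth.states for b in truth.states
            if a != b and (a, b) not in truth.true_transitions
        ]
        eng_variants, naive_variants = [], []
        for k in range(n_variants):
            rng = np.random.default_rng([seed, 5, k])
            n_spur = max(1, len(true_sorted))
            pick = rng.choice(len(all_pairs), size=min(n_spur, len(all_pairs)),
                              replace=False)
            spurious = [all_pairs[i] for i in sorted(pick)]
            combined = true_sorted + spurious
            all_titles = dict(titles)
            for t in spurious:
                all_titles[t] = _fabricated_titles(rng)
            eng_variants.append(_hypothesis_block(combined, all_titles))
            naive_variants.append(_hypothesis_block(combined, None))
        eng_resp, naive_resp = eng_variants, naive_variants
        claim = _fenced([f"TITLE: {t}" for t in _fabricated_titles(np.random.default_rng([seed, 6]))])
    else:  # adversarial
        broken = [
            "no fence at all, just prose",
            _fenced(["GARBAGE LINE THAT MATCHES NOTHING"]),
            _fenced(["TRANSITION: A ->"]),
            _fenced(["RATIONALE: orphan rationale"]),
            _fenced(["TRANSITION: nonsense without an arrow"]),
            _fenced(["TITLE: orphan title before any transition"]),
        ]
        eng_resp = naive_resp = broken
        claim = "completely unfenced claim response"

    return [
        {"contains": "Template: engineered-hypothesis-v1", "response": eng_resp},
        {"contains": "Template: naive-hypothesis-v1", "response": naive_resp},
        {"contains": "Template: claim-citations-v1", "response": claim},
        {"contains": "Template: explain-v1",
         "response": "Mock interpretation: the top-ranked results recapitulate "
                     "the planted signal along the lineage."},
        {"contains": "", "response": "Mock response."},
    ]


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full offline fixture bundle for a spec into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells, traj, truth = make_trajectory(spec)
    pt = compute_pseudotime(traj, truth.root_milestone)
    counts, truth = simulate_counts(spec, cells, pt, truth)

    paths = write_dataset(cells, counts, traj, out)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth.to_json(), indent=1))
    gmt_path = out / "sets.gmt"
    write_gmt(make_gene_sets(truth, counts.genes, seed=spec.seed), gmt_path)
    fixture_path = out / "pubmed_fixture.json"
    fixture_path.write_text(json.dumps(make_pubmed_fixture(truth, seed=spec.seed), indent=1))
    script_path = out / "llm_script.json"
    script_path.write_text(json.dumps(make_llm_script(truth, "faithful", seed=spec.seed), indent=1))
    noisy_path = out / "llm_script_noisy.json"
    noisy_path.write_text(json.dumps(make_llm_script(truth, "noisy", seed=spec.seed), indent=1))

    paths.update({
        "truth": truth_path,
        "gmt": gmt_path,
        "pubmed_fixture": fixture_path,
        "llm_script": script_path,
        "llm_script_noisy": noisy_path,
    })
    return paths
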