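import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from evocell import (
    CellRegion,
    FixturePubMedClient,
    MockProvider,
    SyntheticSpec,
    compute_pseudotime,
    make_llm_script,
    make_pubmed_fixture,
    make_trajectory,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Default-spec synthetic dataset with ground truth and pseudotime."""
    spec = SyntheticSpec(seed=11)
    cells, traj, truth = make_trajectory(spec)
    pt = compute_pseudotime(traj, truth.root_milestone)
    counts, truth = simulate_counts(spec, cells, pt, truth)
    return {"spec": spec, "cells": cells, "traj": traj, "truth": truth,
            "pt": pt, "counts": counts}


@pytest.fixture(scope="session")
def dge_bundle():
    """Two-milestone fixture dedicated to DGE: 50 cells/region, 20 planted
    4-fold genes, NB dispersion 0.1."""
    spec = SyntheticSpec(seed=5, n_milestones=2, n_states=2,
                         cells_per_milestone=50, n_genes=500,
                         n_de_genes=20, n_driver_genes=0)
    cells, traj, truth = make_trajectory(spec)
    pt = compute_pseudotime(traj, truth.root_milestone)
    counts, truth = simulate_counts(spec, cells, pt, truth)
    region_a = CellRegion("A", set(truth.de_region_cells))
    region_b = CellRegion("B", set(cells.cell_id) - truth.de_region_cells)
    return {"counts": counts, "region_a": region_a, "region_b": region_b,
            "truth": truth}


@pytest.fixture(scope="session")
def pubmed_client(default_bundle):
    records = make_pubmed_fixture(default_bundle["truth"], n_decoys=10, seed=11)
    return FixturePubMedClient(records)


@pytest.fixture(scope="session")
def faithful_provider(default_bundle):
    return MockProvider(make_llm_script(default_bundle["truth"], "faithful", seed=11))


@pytest.fixture(scope="session")
def noisy_provider(default_bundle):
    return MockProvider(make_llm_script(default_bundle["truth"], "noisy", seed=11))


@pytest.fixture()
def written_dataset(tmp_path, default_bundle):
    from evocell import write_dataset

    return write_dataset(default_bundle["cells"], default_bundle["counts"],
                         default_bundle["traj"], tmp_path)
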