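"""Loading, validation and annotation of trajectory dataset exports.

A dataset is the CSV triplet produced when a Monocle3 ``cell_data_set`` is
flattened for downstream tools:

* ``metadata.csv`` — one row per cell: ``cell_id,cell_state[,covariate...]``
* ``counts.csv``   — wide genes x cells matrix: first column ``gene_id``,
  one column per cell, nonnegative integer counts (a MatrixMarket ``.mtx``
  plus ``genes``/``cells`` index files is accepted as an alternate layout)
* ``trajectory.csv`` — a sectioned CSV with ``[vertices]`` (milestone id and
  2-D embedding coordinates), ``[edges]`` (undirected, optional length
  weight) and ``[assignment]`` (cell -> milestone)

Each milestone is annotated with its most prevalent cell state, the label
under which lineage endpoints are later matched.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValueError, IntegrityError, SchemaError

UNASSIGNED = "unassigned"

_TRAJ_SECTIONS = ("vertices", "edges", "assignment")


@dataclass
class CellTable:
    """Per-cell metadata: unique cell ids, a cell-state label, covariates."""

    cell_id: list[str]
    cell_state: dict[str, str]
    covariates: pd.DataFrame  # indexed by cell_id; may have zero columns

    def __post_init__(self) -> None:
        if len(set(self.cell_id)) != len(self.cell_id):
            dupes = pd.Series(self.cell_id)
            offenders = sorted(dupes[dupes.duplicated()].unique())
            raise IntegrityError(f"duplicate cell ids: {offenders}")
        for cid in self.cell_id:
            if not cid:
                raise SchemaError("empty cell_id")
            state = self.cell_state.get(cid, "")
            if not isinstance(state, str) or not state:
                raise SchemaError(f"cell {cid!r} has empty cell_state")

    @property
    def n_cells(self) -> int:
        return len(self.cell_id)

    def states(self) -> list[str]:
        """Sorted inventory of distinct cell-state labels."""
        return sorted(set(self.cell_state.values()))


@dataclass
class CountMatrix:
    """Raw counts, genes x cells, with upper-cased unique gene symbols."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # int64, shape (n_genes, n_cells)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise DataValueError(
                f"count matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.cells)) != len(self.cells):
            raise IntegrityError("duplicate cell ids in count matrix")
        upper = [g.upper() for g in self.genes]
        if len(set(upper)) != len(upper):
            s = pd.Series(upper)
            offenders = sorted(s[s.duplicated()].unique())
            raise IntegrityError(
                f"duplicate gene symbols after case normalization: {offenders}"
            )
        self.genes = upper
        self._check_counts()
        self.values = self.values.astype(np.int64)

    def _check_counts(self) -> None:
        vals = self.values
        if not np.issubdtype(vals.dtype, np.integer):
            frac = np.modf(vals)[0]
            bad = np.argwhere((frac != 0) | np.isnan(vals))
            if bad.size:
                i, j = bad[0]
                raise DataValueError(
                    f"non-integer count {vals[i, j]!r} at gene "
                    f"{self.genes[i]!r}, cell {self.cells[j]!r}"
                )
        neg = np.argwhere(vals < 0)
        if neg.size:
            i, j = neg[0]
            raise DataValueError(
                f"negative count {vals[i, j]} at gene {self.genes[i]!r}, "
                f"cell {self.cells[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


@dataclass
class TrajectoryGraph:
    """Principal-graph export: milestones with 2-D coordinates, undirected
    weighted edges, and a cell -> milestone assignment."""

    coordinates: dict[str, tuple[float, float]]
    edges: list[tuple[str, str, float]]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.coordinates:
            raise SchemaError("trajectory declares no milestones")
        for a, b, w in self.edges:
            for m in (a, b):
                if m not in self.coordinates:
                    raise IntegrityError(f"edge endpoint {m!r} is not a declared milestone")
            if w < 0:
                raise DataValueError(f"negative edge weight {w} on edge ({a!r}, {b!r})")
        for cid, m in self.assignment.items():
            if m not in self.coordinates:
                raise IntegrityError(
                    f"cell {cid!r} assigned to undeclared milestone {m!r}"
                )

    @property
    def milestones(self) -> list[str]:
        return sorted(self.coordinates)

    @property
    def n_milestones(self) -> int:
        return len(self.coordinates)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def cells_of(self, milestone: str) -> list[str]:
        return sorted(c for c, m in self.assignment.items() if m == milestone)


@dataclass
class MilestoneAnnotation:
    """A milestone's cell-state census and its most prevalent state."""

    milestone_id: str
    prevalent_state: str
    state_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return sum(self.state_counts.values())


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_metadata(path: str | Path) -> CellTable:
    df = _read_csv(path, "metadata")
    for col in ("cell_id", "cell_state"):
        if col not in df.columns:
            raise SchemaError(f"metadata is missing required column {col!r}")
    cell_ids = df["cell_id"].tolist()
    states = dict(zip(cell_ids, df["cell_state"]))
    cov_cols = [c for c in df.columns if c not in ("cell_id", "cell_state")]
    covariates = df.set_index("cell_id")[cov_cols]
    return CellTable(cell_id=cell_ids, cell_state=states, covariates=covariates)


def read_counts(path: str | Path) -> CountMatrix:
    """Read the wide genes x cells CSV (or ``.mtx`` with sibling index files)."""
    path = Path(path)
    if path.suffix == ".mtx":
        return _read_counts_mtx(path)
    df = _read_csv(path, "counts")
    if "gene_id" not in df.columns:
        raise SchemaError("counts is missing required column 'gene_id'")
    genes = df["gene_id"].tolist()
    cells = [c for c in df.columns if c != "gene_id"]
    raw = df[cells]
    try:
        vals = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValueError(f"non-numeric count in counts matrix: {exc}") from exc
    return CountMatrix(genes=genes, cells=cells, values=vals)


def _read_counts_mtx(path: Path) -> CountMatrix:
    from scipy.io import mmread

    genes_path = path.with_suffix(".genes.txt")
    cells_path = path.with_suffix(".cells.txt")
    for p, what in ((genes_path, "genes index"), (cells_path, "cells index")):
        if not p.exists():
            raise SchemaError(f"{what} file not found: {p}")
    mat = mmread(str(path)).toarray()
    genes = genes_path.read_text().split()
    cells = cells_path.read_text().split()
    return CountMatrix(genes=genes, cells=cells, values=mat)


def read_trajectory(path: str | Path) -> TrajectoryGraph:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"trajectory file not found: {path}")
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            current = stripped[1:-1]
            sections[current] = []
        elif current is not None and stripped:
            sections[current].append(line)
    for name in _TRAJ_SECTIONS:
        if name not in sections:
            raise SchemaError(f"trajectory is missing required section [{name}]")

    def frame(name: str) -> pd.DataFrame:
        return pd.read_csv(
            _io.StringIO("\n".join(sections[name])), dtype=str, keep_default_na=False
        )

    verts = frame("vertices")
    for col in ("milestone_id", "x", "y"):
        if col not in verts.columns:
            raise SchemaError(f"trajectory [vertices] is missing column {col!r}")
    coordinates = {
        r.milestone_id: (float(r.x), float(r.y)) for r in verts.itertuples()
    }

    edges_df = frame("edges")
    for col in ("from", "to"):
        if col not in edges_df.columns:
            raise SchemaError(f"trajectory [edges] is missing column {col!r}")
    edges = []
    for _, row in edges_df.iterrows():
        # absent weight means a hop metric
        w = float(row["weight"]) if "weight" in edges_df.columns and row["weight"] != "" else 1.0
        edges.append((row["from"], row["to"], w))

    assign_df = frame("assignment")
    for col in ("cell_id", "milestone_id"):
        if col not in assign_df.columns:
            raise SchemaError(f"trajectory [assignment] is missing column {col!r}")
    assignment = dict(zip(assign_df["cell_id"], assign_df["milestone_id"]))

    return TrajectoryGraph(coordinates=coordinates, edges=edges, assignment=assignment)


def load_dataset(
    metadata_path: str | Path,
    counts_path: str | Path,
    trajectory_path: str | Path,
) -> tuple[CellTable, CountMatrix, TrajectoryGraph]:
    """Load and cross-validate the dataset triplet.

    Every cell referenced by the count matrix or the trajectory assignment
    must exist in the metadata; cells present only in the metadata are
    retained (Monocle3 can drop cells from the principal graph).
    """
    cells = read_metadata(metadata_path)
    counts = read_counts(counts_path)
    traj = read_trajectory(trajectory_path)

    known = set(cells.cell_id)
    unknown_counts = sorted(set(counts.cells) - known)
    if unknown_counts:
        raise IntegrityError(
            f"count matrix references cells absent from metadata: {unknown_counts}"
        )
    unknown_assign = sorted(set(traj.assignment) - known)
    if unknown_assign:
        raise IntegrityError(
            f"trajectory assignment references cells absent from metadata: {unknown_assign}"
        )
    return cells, counts, traj


def write_dataset(
    cells: CellTable,
    counts: CountMatrix,
    traj: TrajectoryGraph,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the triplet back to CSV; inverse of :func:`load_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    meta = pd.DataFrame({"cell_id": cells.cell_id})
    meta["cell_state"] = [cells.cell_state[c] for c in cells.cell_id]
    for col in cells.covariates.columns:
        meta[col] = cells.covariates.loc[cells.cell_id, col].to_numpy()
    meta_path = out / "metadata.csv"
    meta.to_csv(meta_path, index=False)

    counts_path = out / "counts.csv"
    cdf = counts.to_frame()
    cdf.insert(0, "gene_id", cdf.index)
    cdf.to_csv(counts_path, index=False)

    traj_path = out / "trajectory.csv"
    with open(traj_path, "w") as fh:
        fh.write("[vertices]\nmilestone_id,x,y\n")
        for m in sorted(traj.coordinates):
            x, y = traj.coordinates[m]
            fh.write(f"{m},{x},{y}\n")
        fh.write("[edges]\nfrom,to,weight\n")
        for a, b, w in traj.edges:
            fh.write(f"{a},{b},{w}\n")
        fh.write("[assignment]\ncell_id,milestone_id\n")
        for cid in sorted(traj.assignment):
            fh.write(f"{cid},{traj.assignment[cid]}\n")

    return {"metadata": meta_path, "counts": counts_path, "trajectory": traj_path}


def annotate_milestones(
    cells: CellTable, traj: TrajectoryGraph
) -> list[MilestoneAnnotation]:
    """Associate each milestone with its most prevalent cell state.

    Ties break to the lexicographically smallest state label; milestones
    with no assigned cells carry the sentinel state ``"unassigned"``.
    """
    census: dict[str, dict[str, int]] = {m: {} for m in traj.coordinates}
    for cid, m in traj.assignment.items():
        state = cells.cell_state[cid]
        census[m][state] = census[m].get(state, 0) + 1
    annotations = []
    for m in sorted(traj.coordinates):
        counts = census[m]
        if counts:
            prevalent = min(counts, key=lambda s: (-counts[s], s))
        else:
            prevalent = UNASSIGNED
        annotations.append(
            MilestoneAnnotation(milestone_id=m, prevalent_state=prevalent, state_counts=counts)
        )
    return annotations


def dataset_summary(
    cells: CellTable, counts: CountMatrix, traj: TrajectoryGraph
) -> dict:
    """Small JSON-serializable summary of a loaded dataset."""
    summary = {
        "n_cells": cells.n_cells,
        "n_genes": counts.n_genes,
        "n_milestones": traj.n_milestones,
        "n_edges": traj.n_edges,
        "n_assigned_cells": len(traj.assignment),
        "states": cells.states(),
    }
    if len(cells.covariates.columns):
        summary["covariates"] = sorted(cells.covariates.columns)
    return summary
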