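"""Preranked gene-set enrichment analysis, implemented from scratch.

The statistic is the weighted Kolmogorov–Smirnov running sum over a ranked
gene list: walking down the list, genes in the set add |score|^p normalized
by the in-set total, genes outside subtract 1/(N - N_set); the enrichment
score (ES) is the extremum of the walk. Significance comes from a gene-set
permutation null (uniformly random same-size sets), ES is normalized to NES
by the sign-matched null mean, and FDR q-values use the sign-stratified
ratio-of-tails over pooled null NES, clamped to [0, 1] with a monotonicity
pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GmtParseError, ParameterError
from .expression import DGEResult

_P_FLOOR = 1e-300  # clamp for p = 0 before -log10


@dataclass
class RankedList:
    """Genes with scores in strictly decreasing (score, then name) order."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ParameterError("genes and scores differ in length")
        if np.any(~np.isfinite(self.scores)):
            raise ParameterError("ranked scores contain NaN/inf")
        self.genes = [g.upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("duplicate gene symbols in ranked list")
        order = sorted(range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSet:
    name: str
    members: set[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError(f"gene set {self.name!r} is empty")
        self.members = {m.upper() for m in self.members}


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    n_overlap: int
    leading_edge: list[str] = field(default_factory=list)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read tab-separated gene sets: name, description, member genes."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"GMT line {lineno} has {len(fields)} fields; need name, "
                f"description and at least one member",
                line_number=lineno,
            )
        name, description, *members = fields
        members = [m for m in members if m]
        if not members:
            raise GmtParseError(f"GMT line {lineno} has no members", line_number=lineno)
        sets.append(GeneSet(name=name, description=description, members=set(members)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
    return path


def make_ranked_list(
    dge: list[DGEResult], metric: str = "signed_logp"
) -> RankedList:
    """Rank genes for preranked GSEA.

    ``signed_logp`` (default): sign(log2fc) * -log10(p), with p clamped at
    1e-300; ``log2fc``: the fold change itself.
    """
    if not dge:
        raise ParameterError("empty DGE table")
    if metric == "signed_logp":
        scores = [
            float(np.sign(r.log2fc) * -np.log10(max(r.p_value, _P_FLOOR))) for r in dge
        ]
    elif metric == "log2fc":
        scores = [r.log2fc for r in dge]
    else:
        raise ParameterError(f"unknown ranking metric {metric!r}")
    return RankedList(genes=[r.gene.upper() for r in dge], scores=np.asarray(scores))


def _hit_weights(scores: np.ndarray, weight_p: float) -> np.ndarray:
    return np.abs(scores) ** weight_p


def enrichment_score(
    ranked: RankedList, set_: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running sum; returns (es, running_sum, leading_edge)."""
    n = len(ranked)
    hits = np.asarray([g in set_.members for g in ranked.genes], dtype=bool)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ParameterError(f"gene set {set_.name!r} has no overlap with the ranked list")
    if n_hit == n:
        raise ParameterError(f"gene set {set_.name!r} covers the whole ranked list")
    running = _running_sum(ranked.scores, hits, weight_p)
    pos = int(np.argmax(np.abs(running)))
    es = float(np.clip(running[pos], -1.0, 1.0))  # guard one-ulp overshoot
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if hits[i] and i <= pos]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if hits[i] and i >= pos]
    return es, running, leading


def _running_sum(scores: np.ndarray, hits: np.ndarray, weight_p: float) -> np.ndarray:
    n = len(scores)
    n_hit = int(hits.sum())
    w = _hit_weights(scores, weight_p)
    nr = w[hits].sum()
    if nr == 0:  # all in-set scores are exactly zero: fall back to equal mass
        inc = np.where(hits, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        inc = np.where(hits, w / nr, -1.0 / (n - n_hit))
    return np.cumsum(inc)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    weight_p: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ES values of ``n_perm`` uniformly random gene sets of ``set_size``."""
    n = len(ranked)
    if not 0 < set_size < n:
        raise ParameterError(f"set_size must be in (0, {n}), got {set_size}")
    if n_perm < 100:
        raise ParameterError(f"n_perm must be >= 100, got {n_perm}")
    if rng is None:
        rng = np.random.default_rng(seed)
    w = _hit_weights(ranked.scores, weight_p)
    out = np.empty(n_perm, dtype=float)
    chunk = max(1, min(n_perm, int(4e6 // max(n, 1)) or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m random size-k subsets as boolean hit masks
        pick = np.argpartition(rng.random((m, n)), set_size - 1, axis=1)[:, :set_size]
        hits = np.zeros((m, n), dtype=bool)
        hits[np.arange(m)[:, None], pick] = True
        wh = np.where(hits, w, 0.0)
        nr = wh.sum(axis=1, keepdims=True)
        nr[nr == 0] = 1.0
        inc = np.where(hits, wh / nr, -1.0 / (n - set_size))
        # degenerate all-zero-weight sets: equal hit mass
        zero = (wh.sum(axis=1) == 0)
        if zero.any():
            inc[zero] = np.where(hits[zero], 1.0 / set_size, -1.0 / (n - set_size))
        rs = np.cumsum(inc, axis=1)
        idx = np.argmax(np.abs(rs), axis=1)
        out[done : done + m] = np.clip(rs[np.arange(m), idx], -1.0, 1.0)
        done += m
    return out


def _nes(es: float | np.ndarray, null: np.ndarray) -> np.ndarray:
    """Normalize ES by the mean |null ES| of matching sign."""
    es = np.atleast_1d(np.asarray(es, dtype=float))
    pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
    neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
    out = np.where(es >= 0, es / pos_mean, es / neg_mean)
    return np.where(np.isfinite(out), out, 0.0)


def run_gsea(
    dge: list[DGEResult],
    gmt_path: str | Path,
    min_size: int = 5,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    metric: str = "signed_logp",
) -> list[GseaResult]:
    """Preranked GSEA of a DGE table against a GMT collection.

    Sets are intersected with the ranked universe before size filtering.
    Per set: ES, sign-matched NES, empirical two-tail p, and a
    sign-stratified ratio-of-tails FDR q over the pooled null NES.
    Results are sorted by (fdr_q, |nes| descending).
    """
    ranked = make_ranked_list(dge, metric=metric)
    universe = set(ranked.genes)
    gene_sets = read_gmt(gmt_path)

    kept: list[tuple[GeneSet, int]] = []
    for s in gene_sets:
        overlap = len(s.members & universe)
        if min_size <= overlap <= max_size and overlap < len(ranked):
            kept.append((s, overlap))
    if not kept:
        return []

    # one permutation null per distinct overlap size, deterministic in seed
    rng = np.random.default_rng(seed)
    sizes = sorted({k for _, k in kept})
    nulls = {k: permutation_null(ranked, k, n_perm, weight_p, rng=rng) for k in sizes}

    names, es_vals, nes_vals, p_vals, overlaps, leading = [], [], [], [], [], []
    null_nes_pool: list[np.ndarray] = []
    for s, k in kept:
        es, _, le = enrichment_score(ranked, s, weight_p)
        null = nulls[k]
        nes = float(_nes(es, null)[0])
        p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        names.append(s.name)
        es_vals.append(es)
        nes_vals.append(nes)
        p_vals.append(float(p))
        overlaps.append(k)
        leading.append(le)
    for k in sizes:
        null_nes_pool.append(_nes(nulls[k], nulls[k]))
    null_nes = np.concatenate(null_nes_pool)
    obs_nes = np.asarray(nes_vals)

    q = _ratio_of_tails_fdr(obs_nes, null_nes)

    results = [
        GseaResult(
            set_name=names[i],
            es=float(es_vals[i]),
            nes=float(obs_nes[i]),
            p_value=p_vals[i],
            fdr_q=float(q[i]),
            n_overlap=overlaps[i],
            leading_edge=leading[i],
        )
        for i in range(len(names))
    ]
    results.sort(key=lambda r: (r.fdr_q, -abs(r.nes), r.set_name))
    return results


def _ratio_of_tails_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified ratio-of-tails FDR with clamping and monotonicity."""
    q = np.ones_like(obs_nes, dtype=float)
    for sign in (1, -1):
        stratum = np.flatnonzero((obs_nes >= 0) if sign == 1 else (obs_nes < 0))
        if stratum.size == 0:
            continue
        null_side = null_nes[null_nes >= 0] if sign == 1 else null_nes[null_nes < 0]
        obs_side = obs_nes[stratum]
        for j, i in enumerate(stratum):
            thr = abs(obs_nes[i])
            null_frac = (
                np.count_nonzero(np.abs(null_side) >= thr) / null_side.size
                if null_side.size
                else 1.0
            )
            obs_frac = np.count_nonzero(np.abs(obs_side) >= thr) / obs_side.size
            q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        # monotone: a more extreme |NES| never gets a larger q
        order = stratum[np.argsort(-np.abs(obs_nes[stratum]), kind="stable")]
        q[order] = np.minimum.accumulate(q[order[::-1]])[::-1]
    return q
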