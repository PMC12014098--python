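"""Independent brute-force oracles used to check the package's algorithms.

These deliberately share no code with the implementation: plain-python
flood fill, exhaustive DFS, Bellman–Ford, direct running-sum evaluation,
the textbook BH step-up formula, and an all-substrings common-run scan.
"""

from __future__ import annotations

import math


def flood_fill_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adj[n] - comp)
        seen |= comp
        components.append(comp)
    return components


def dfs_simple_paths(
    nodes: list[str],
    edges: list[tuple[str, str]],
    sources: set[str],
    targets: set[str],
    max_length: int,
) -> list[list[str]]:
    """All simple paths from any source to any target with <= max_length edges."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out: list[list[str]] = []

    def walk(path: list[str]) -> None:
        node = path[-1]
        if node in targets and len(path) > 1:
            out.append(list(path))
        if len(path) - 1 >= max_length:
            return
        for nxt in sorted(adj[node]):
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    for src in sorted(sources):
        walk([src])
    return out


def hop_ball(nodes: list[str], edges: list[tuple[str, str]], seeds: set[str],
             radius: int) -> set[str]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    frontier = set(seeds)
    ball = set(seeds)
    for _ in range(radius):
        frontier = {m for n in frontier for m in adj[n]} - ball
        ball |= frontier
    return ball


def bellman_ford(nodes: list[str], edges: list[tuple[str, str, float]],
                 origin: str) -> dict[str, float]:
    dist = {n: math.inf for n in nodes}
    dist[origin] = 0.0
    for _ in range(len(nodes) - 1):
        changed = False
        for a, b, w in edges:
            for u, v in ((a, b), (b, a)):
                if dist[u] + w < dist[v]:
                    dist[v] = dist[u] + w
                    changed = True
        if not changed:
            break
    return dist


def bh_stepup(p_values: list[float]) -> list[float]:
    """Textbook Benjamini–Hochberg: p(i) * m / i with cumulative minimum."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def brute_enrichment_score(scores: list[float], in_set: list[bool],
                           weight_p: float) -> float:
    """Direct loop evaluation of the weighted KS running sum extremum."""
    n = len(scores)
    n_hit = sum(in_set)
    nr = sum(abs(s) ** weight_p for s, h in zip(scores, in_set) if h)
    total = 0.0
    best = 0.0
    for s, h in zip(scores, in_set):
        if h:
            total += (abs(s) ** weight_p) / nr if nr > 0 else 1.0 / n_hit
        else:
            total -= 1.0 / (n - n_hit)
        if abs(total) > abs(best):
            best = total
    return best


def unweighted_ks_extremes(scores: list[float], in_set: list[bool]) -> tuple[float, float]:
    """Classical KS walk: the most positive and most negative deviations of
    the hit CDF over the miss CDF. Returned separately because the signed
    extremum is ambiguous when the two peaks tie in magnitude."""
    n_hit = sum(in_set)
    n_miss = len(in_set) - n_hit
    f_hit = f_miss = 0.0
    peak_pos = peak_neg = 0.0
    for h in in_set:
        if h:
            f_hit += 1.0 / n_hit
        else:
            f_miss += 1.0 / n_miss
        d = f_hit - f_miss
        peak_pos = max(peak_pos, d)
        peak_neg = min(peak_neg, d)
    return peak_pos, peak_neg


def longest_common_run(a: list[str], b: list[str]) -> int:
    """All-substrings scan for the longest common contiguous run."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            best = max(best, k)
    return best


def sample_sd(values: list[float]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
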