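"""Brute-force graph oracles, independent of the package implementation.

These deliberately avoid networkx (and any shared code path with
``mixs_sa.relgraph``): cycles are found by enumerating simple paths, and
closures by repeated single-step expansion to a fixpoint.
"""

from __future__ import annotations

import random


def brute_force_has_cycle(nodes: list[str], edges: set[tuple[str, str]]) -> bool:
    """True iff some directed simple path can be closed by one more edge."""
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        succ[a].append(b)

    def extend(path: list[str]) -> bool:
        for nxt in succ[path[-1]]:
            if nxt == path[0]:
                return True
            if nxt not in path and extend(path + [nxt]):
                return True
        return False

    return any(extend([n]) for n in nodes)


def fixpoint_closure(start: str, edges: set[tuple[str, str]]) -> set[str]:
    """Nodes reachable from ``start`` by naive repeated one-step expansion."""
    reached: set[str] = set()
    frontier = {start}
    while frontier:
        step = {b for (a, b) in edges if a in frontier} - reached - {start}
        reached |= step
        frontier = step
    return reached


def fixpoint_closure_reverse(target: str, edges: set[tuple[str, str]]) -> set[str]:
    return fixpoint_closure(target, {(b, a) for (a, b) in edges})


def bfs_levels(start: str, edges: set[tuple[str, str]]) -> list[str]:
    """Breadth-first reachability order (ties sorted), duplicates removed."""
    order: list[str] = []
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = sorted(
            {b for (a, b) in edges if a in frontier} - seen
        )
        order.extend(nxt)
        seen |= set(nxt)
        frontier = nxt
    return order


def random_digraph(rng: random.Random, max_nodes: int = 8) -> tuple[list[str], set[tuple[str, str]]]:
    """A random small digraph over single-letter node names."""
    n = rng.randint(2, max_nodes)
    nodes = [chr(ord("A") + i) for i in range(n)]
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    density = rng.uniform(0.05, 0.4)
    edges = {p for p in pairs if rng.random() < density}
    return nodes, edges
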