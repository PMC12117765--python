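"""Shared test utilities: tiny DAG builders and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths (and scipy
where the oracle is the point): reachability is recursive set union,
hypergeometric tails are counted by enumerating draws, and the adjustment
procedures are written directly from their step-up/step-down definitions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from mycoenrich.ontology import GoDag

BP = "biological_process"


def make_dag(edges: list[tuple[str, str, str]], namespace: str = BP,
             extra_terms: list[str] | None = None) -> GoDag:
    """Build a GoDag from (child, parent, relation) triples."""
    terms = {t for e in edges for t in e[:2]} | set(extra_terms or [])
    parent_edges: dict[str, set[tuple[str, str]]] = {t: set() for t in terms}
    for child, parent, relation in edges:
        parent_edges[child].add((parent, relation))
    return GoDag(
        terms=terms,
        names={t: f"name of {t}" for t in terms},
        namespaces={t: namespace for t in terms},
        parent_edges=parent_edges,
    )


def chain_dag() -> GoDag:
    """C is_a B is_a A."""
    return make_dag([("C", "B", "is_a"), ("B", "A", "is_a")])


def diamond_dag() -> GoDag:
    """D is_a B, D is_a C, B is_a A, C is_a A."""
    return make_dag([("D", "B", "is_a"), ("D", "C", "is_a"),
                     ("B", "A", "is_a"), ("C", "A", "is_a")])


def random_dag(rng: np.random.Generator, n_nodes: int, namespace: str = BP,
               second_parent_prob: float = 0.4) -> GoDag:
    """Random single-namespace DAG: node i only points at earlier nodes."""
    ids = [f"GO:{9000000 + i:07d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parent = ids[int(rng.integers(0, i))]
        rel = "part_of" if rng.random() < 0.2 else "is_a"
        edges.append((ids[i], parent, rel))
        if i >= 2 and rng.random() < second_parent_prob:
            other = ids[int(rng.integers(0, i))]
            if other != parent:
                edges.append((ids[i], other, "is_a"))
    return make_dag(edges, namespace=namespace, extra_terms=ids)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def reachability_oracle(dag: GoDag, term: str) -> set[str]:
    """Reflexive upward reachability by naive recursion."""
    out = {term}
    for parent, _rel in dag.parent_edges.get(term, ()):
        out |= reachability_oracle(dag, parent)
    return out


def upward_within_oracle(dag: GoDag, term: str, depth: int) -> set[str]:
    """Nodes within `depth` upward hops, by naive expansion."""
    frontier, seen = {term}, {term}
    for _ in range(depth):
        frontier = {p for t in frontier for p, _ in dag.parent_edges.get(t, ())}
        seen |= frontier
    return seen


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every draw of n items from N."""
    successes = set(range(K))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def bh_oracle(ps: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j, clamped."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * ps[i] / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def bonferroni_oracle(ps: list[float]) -> list[float]:
    return [min(1.0, len(ps) * p) for p in ps]


def holm_oracle(ps: list[float]) -> list[float]:
    """Holm step-down: cummax of (m-rank+1)*p_(rank), clamped."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, (m - rank + 1) * ps[i])
        adjusted[i] = min(1.0, running)
    return adjusted
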