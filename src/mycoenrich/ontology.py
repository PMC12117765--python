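"""Gene Ontology DAG: ancestry, depth, annotation propagation, term grouping.

The GO is held as a directed acyclic graph whose edges point from a term to
its parents (``is_a`` and ``part_of``). Annotation propagation follows the
true-path rule: a protein annotated to a term is implicitly annotated to
every ancestor of that term, so general terms inherit the annotations of
their more specific descendants. All queries are confined to the term's
namespace — the three GO namespaces are independent sub-ontologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .annotation_io import AnnotationRecord

__all__ = ["GoDag", "ancestors", "term_depth", "propagate_annotations", "grouped_by_shared_ancestor"]

RELATIONS = ("is_a", "part_of")


@dataclass
class GoDag:
    """A GO term DAG with names, namespaces and alias resolution.

    ``parent_edges`` maps each term to its set of ``(parent, relation)``
    pairs; ``aliases`` maps secondary (``alt_id``) accessions to primary
    term ids. Acyclicity and referential closure are verified at
    construction.
    """

    terms: set[str]
    names: dict[str, str]
    namespaces: dict[str, str]
    parent_edges: dict[str, set[tuple[str, str]]]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, edges in self.parent_edges.items():
            if term not in self.terms:
                raise ValueError(f"edge source {term!r} is not a term")
            for parent, relation in edges:
                if parent not in self.terms:
                    raise ValueError(f"parent {parent!r} of {term!r} is not a term")
                if relation not in RELATIONS:
                    raise ValueError(f"unsupported relation {relation!r}")
        graph = self._graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def _graph(self, relations: Sequence[str] = RELATIONS) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term, edges in self.parent_edges.items():
            for parent, relation in edges:
                if relation in relations:
                    g.add_edge(term, parent)
        return g

    def resolve(self, term: str) -> str:
        """Resolve an accession (or alias) to its primary term id."""
        if term in self.terms:
            return term
        if term in self.aliases:
            return self.aliases[term]
        raise KeyError(f"unknown GO term: {term!r}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.aliases

    def name(self, term: str) -> str:
        return self.names.get(self.resolve(term), term)

    def namespace(self, term: str) -> str:
        return self.namespaces[self.resolve(term)]

    def parents(self, term: str, relations: Sequence[str] = RELATIONS) -> set[str]:
        """Same-namespace parents of a term over the enabled relations."""
        term = self.resolve(term)
        ns = self.namespaces[term]
        return {
            parent
            for parent, relation in self.parent_edges.get(term, ())
            if relation in relations and self.namespaces[parent] == ns
        }

    def roots(self, namespace: str, relations: Sequence[str] = RELATIONS) -> set[str]:
        """Terms of a namespace with no same-namespace parents."""
        return {
            t
            for t in self.terms
            if self.namespaces[t] == namespace and not self.parents(t, relations)
        }


def ancestors(dag: GoDag, term: str, relations: Sequence[str] = RELATIONS) -> set[str]:
    """Reflexive transitive ancestors of ``term`` over the enabled relations.

    The term itself is included (distance 0); the result never leaves the
    term's namespace. Unknown terms raise ``KeyError`` naming the id.
    """
    start = dag.resolve(term)
    seen = {start}
    frontier = [start]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for parent in dag.parents(t, relations):
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return seen


def _upward_within(dag: GoDag, term: str, depth_limit: int,
                   relations: Sequence[str] = RELATIONS) -> set[str]:
    """Terms reachable upward from ``term`` in at most ``depth_limit`` hops."""
    seen = {dag.resolve(term)}
    frontier = set(seen)
    for _ in range(depth_limit):
        frontier = {p for t in frontier for p in dag.parents(t, relations)} - seen
        if not frontier:
            break
        seen |= frontier
    return seen


def term_depth(dag: GoDag, term: str, relations: Sequence[str] = RELATIONS) -> int:
    """Length of the shortest upward path from ``term`` to a namespace root.

    Roots (terms with no same-namespace parents) have depth 0.
    """
    depth = 0
    frontier = {dag.resolve(term)}
    seen = set(frontier)
    while frontier:
        if any(not dag.parents(t, relations) for t in frontier):
            return depth
        frontier = {p for t in frontier for p in dag.parents(t, relations)} - seen
        seen |= frontier
        depth += 1
    raise RuntimeError("unreachable: DAG must contain a parentless ancestor")


def propagate_annotations(
    dag: GoDag,
    records: Iterable[AnnotationRecord],
    relations: Sequence[str] = RELATIONS,
) -> tuple[list[AnnotationRecord], int]:
    """Close GO annotations under ancestry (the true-path rule).

    Every (protein, term) assignment spawns assignments to all ancestors of
    the term; duplicates collapse. Records whose term is absent from the DAG
    (after alias resolution) are dropped and counted. Returns
    ``(propagated_records, n_dropped)``. Idempotent: propagating an already
    propagated record set is a no-op.
    """
    out: dict[tuple[str, str], AnnotationRecord] = {}
    dropped = 0
    for record in records:
        if record.category_id not in dag:
            dropped += 1
            continue
        for term in ancestors(dag, record.category_id, relations):
            key = (record.protein_id, term)
            if key not in out:
                out[key] = AnnotationRecord(
                    protein_id=record.protein_id,
                    category_id=term,
                    category_label=dag.name(term),
                    category_group=dag.namespace(term),
                    source=record.source,
                )
    return list(out.values()), dropped


def grouped_by_shared_ancestor(
    dag: GoDag,
    terms: Iterable[str],
    depth_limit: int,
    relations: Sequence[str] = RELATIONS,
) -> list[set[str]]:
    """Partition terms by the shared-nearby-ancestor relation.

    Two terms are related when some ancestor lies within ``depth_limit``
    upward hops of *each* of them (a term is its own ancestor at distance
    0), and the partition is the connected components of that relation, so
    the result is independent of input order. With ``depth_limit=0`` only
    identical terms group. Namespace roots present in the input are returned
    as singletons and take no part in grouping (a root would otherwise
    absorb every term within ``depth_limit`` of it).

    All terms must belong to one namespace; blocks are returned sorted by
    their smallest member for determinism.
    """
    if depth_limit < 0:
        raise ValueError("depth_limit must be >= 0")
    resolved = sorted({dag.resolve(t) for t in terms})
    if not resolved:
        return []
    spaces = {dag.namespaces[t] for t in resolved}
    if len(spaces) > 1:
        raise ValueError(f"terms span multiple namespaces: {sorted(spaces)}")

    root_singletons = [t for t in resolved if not dag.parents(t, relations)]
    groupable = [t for t in resolved if dag.parents(t, relations)]

    parent: dict[str, str] = {t: t for t in groupable}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    anchor: dict[str, str] = {}  # nearby-ancestor -> first term that reached it
    for t in groupable:
        for a in _upward_within(dag, t, depth_limit, relations):
            if a in anchor:
                union(t, anchor[a])
            else:
                anchor[a] = t

    blocks: dict[str, set[str]] = {}
    for t in groupable:
        blocks.setdefault(find(t), set()).add(t)
    result = [{t} for t in root_singletons] + list(blocks.values())
    return sorted(result, key=min)
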