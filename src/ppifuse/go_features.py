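"""Gene Ontology DAG handling and LCA-anchored cluster features.

The ontology is a rooted DAG per namespace with child-to-parent ``is_a`` /
``part_of`` edges. For a training collection of protein pairs, the lowest
common ancestor (LCA) of each pair's pooled annotation set is computed per
namespace; the deduplicated LCAs, walked deepest-first, carve the DAG into
mutually exclusive clusters (each anchor claims its not-yet-claimed
descendant subgraph). A pair is then represented by one non-negative value
per cluster: the summed node counts of the ascending paths from each
annotated term to its cluster anchor, over the multiset union of the two
proteins' annotation sets.

Conventions: term depth is the LONGEST ascending distance to the namespace
root (the standard GO level convention); the per-term path count to the
anchor uses the SHORTEST ascending path, inclusive of both endpoints, so a
term sitting on its own anchor contributes 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import chain
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

log = logging.getLogger(__name__)


class GoDag:
    """A rooted, acyclic ontology graph with depth and ancestor queries.

    Parameters
    ----------
    edges:
        Child-to-parent edges (``is_a``/``part_of`` collapsed).
    namespaces:
        Map from term id to namespace. Terms absent from ``edges`` but
        present here become isolated roots of their namespace only if no
        other root exists.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], namespaces: Mapping[str, str]):
        self._g = nx.DiGraph()
        self._g.add_nodes_from(namespaces)
        self._g.add_edges_from(edges)
        self._ns = dict(namespaces)
        missing = [n for n in self._g if n not in self._ns]
        if missing:
            raise ValueError(f"terms without a namespace: {sorted(missing)[:5]}")
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        self._roots: dict[str, str] = {}
        for node in self._g:
            if self._g.out_degree(node) == 0:
                ns = self._ns[node]
                if ns in self._roots:
                    raise ValueError(
                        f"namespace {ns!r} has multiple roots: {self._roots[ns]}, {node}"
                    )
                self._roots[ns] = node
        self._depth = self._compute_depths()
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    def _compute_depths(self) -> dict[str, int]:
        # longest ascending path to the root; parents before children in
        # reverse topological order of the child->parent graph
        depth: dict[str, int] = {}
        for node in reversed(list(nx.topological_sort(self._g))):
            parents = list(self._g.successors(node))
            depth[node] = 0 if not parents else max(depth[p] for p in parents) + 1
        return depth

    # -- queries ----------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return len(self._g)

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g)

    @property
    def namespaces(self) -> list[str]:
        return sorted(self._roots)

    def namespace(self, term: str) -> str:
        return self._ns[term]

    def root(self, namespace: str) -> str:
        return self._roots[namespace]

    def depth(self, term: str) -> int:
        return self._depth[term]

    def parents(self, term: str) -> list[str]:
        return sorted(self._g.successors(term))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges())

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor-or-self set of ``term``."""
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._g, term)) | {term}
            self._anc_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """Descendant-or-self set of ``term`` (terms that can ascend to it)."""
        cached = self._desc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self._g, term)) | {term}
            self._desc_cache[term] = cached
        return cached

    def ascending_path_nodes(self, term: str, ancestor: str) -> int:
        """Node count on the shortest ascending path ``term -> ancestor``, inclusive."""
        return nx.shortest_path_length(self._g, term, ancestor) + 1


def lowest_common_ancestor(dag: GoDag, terms: Iterable[str]) -> str:
    """Deepest node that is an ancestor-or-self of every term in ``terms``.

    Ties are broken by lexicographically smallest id. Terms must share a
    namespace; terms with no common ancestor fall back to the namespace root.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("term set is empty")
    namespaces = {dag.namespace(t) for t in terms}
    if len(namespaces) > 1:
        raise ValueError(f"terms span multiple namespaces: {sorted(namespaces)}")
    common = dag.ancestors(terms[0])
    for t in terms[1:]:
        common = common & dag.ancestors(t)
    if not common:
        return dag.root(namespaces.pop())
    return min(common, key=lambda n: (-dag.depth(n), n))


@dataclass
class LcaIndex:
    """The LCA-anchored clustering of the ontology learned from training pairs.

    ``anchors`` is the ordered cluster anchor list (namespace blocks in
    namespace-sorted order, deepest anchors first within each block);
    ``term_to_cluster`` maps every claimed term to its cluster index.
    """

    anchors: list[str]
    anchor_namespaces: list[str]
    term_to_cluster: dict[str, int]
    _path_cache: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    @property
    def m(self) -> int:
        return len(self.anchors)

    def clusters_in(self, namespace: str) -> list[int]:
        return [j for j, ns in enumerate(self.anchor_namespaces) if ns == namespace]

    def path_node_count(self, dag: GoDag, term: str) -> int:
        count = self._path_cache.get(term)
        if count is None:
            anchor = self.anchors[self.term_to_cluster[term]]
            count = dag.ascending_path_nodes(term, anchor)
            self._path_cache[term] = count
        return count

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "anchors": self.anchors,
            "anchor_namespaces": self.anchor_namespaces,
            "term_to_cluster": self.term_to_cluster,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LcaIndex":
        payload = json.loads(Path(path).read_text())
        return cls(
            anchors=list(payload["anchors"]),
            anchor_namespaces=list(payload["anchor_namespaces"]),
            term_to_cluster={k: int(v) for k, v in payload["term_to_cluster"].items()},
        )


def build_lca_index(dag: GoDag, training_pairs, annotations) -> LcaIndex:
    """Cluster the DAG from the LCAs of the training pairs' pooled term sets.

    For each pair the LCA of the union of both proteins' terms is taken per
    namespace; the deduplicated anchors are sorted deepest-first (deeper
    anchors yield smaller, more specific clusters) and each anchor claims its
    descendant subgraph minus already-claimed terms. Clusters are disjoint by
    construction and every anchor belongs to its own cluster. Pairs with no
    annotations on either side are skipped with a warning.
    """
    per_ns_anchors: dict[str, set[str]] = {}
    skipped = 0
    for pair in training_pairs:
        pooled = annotations.terms_for(pair.u) | annotations.terms_for(pair.v)
        if not pooled:
            skipped += 1
            continue
        by_ns: dict[str, list[str]] = {}
        for t in pooled:
            by_ns.setdefault(dag.namespace(t), []).append(t)
        for ns, terms in by_ns.items():
            per_ns_anchors.setdefault(ns, set()).add(lowest_common_ancestor(dag, terms))
    if skipped:
        log.warning("skipped %d training pairs with no annotations on either side", skipped)

    anchors: list[str] = []
    anchor_ns: list[str] = []
    term_to_cluster: dict[str, int] = {}
    for ns in sorted(per_ns_anchors):
        claimed: set[str] = set()
        for anchor in sorted(per_ns_anchors[ns], key=lambda a: (-dag.depth(a), a)):
            if anchor in claimed:
                continue
            members = dag.descendants(anchor) - claimed
            claimed |= members
            idx = len(anchors)
            anchors.append(anchor)
            anchor_ns.append(ns)
            for t in members:
                term_to_cluster[t] = idx
    return LcaIndex(anchors=anchors, anchor_namespaces=anchor_ns, term_to_cluster=term_to_cluster)


def go_feature_vector(index: LcaIndex, dag: GoDag, gu: Iterable[str], gv: Iterable[str]):
    """Per-pair GO feature vector of length ``index.m``.

    Each term occurrence in the multiset union of ``gu`` and ``gv`` (terms
    annotated to both proteins count twice) adds the node count of its
    shortest ascending path to its cluster anchor, inclusive of both
    endpoints. Terms outside every cluster contribute nothing; an
    unannotated pair yields the zero vector.
    """
    import numpy as np

    vec = np.zeros(index.m)
    for term in chain(gu, gv):
        j = index.term_to_cluster.get(term)
        if j is None:
            continue
        vec[j] += index.path_node_count(dag, term)
    return vec
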