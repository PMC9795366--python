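"""Side-information similarity graphs.

Two constructions are supported:

* Jaccard similarity between discrete feature sets (protein targets,
  indication terms, or fingerprint on-bit positions — for binary structural
  fingerprints the Jaccard index is the 2D Tanimoto chemical similarity).
* Taxonomy similarity from a code hierarchy (ATC for drugs, MedDRA for side
  effects): ``1 - SP(u, v) / max_pair SP`` where SP is the shortest
  undirected path length in the hierarchy between the two entities'
  annotation sets, minimized over all cross pairs of codes, and the
  normalizer is the empirical maximum over all annotated entity pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import AbstractSet, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import SimilarityGraph, _unique_ids
from .exceptions import DegenerateInputError, IdentifierError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSets:
    """Discrete feature tokens per entity (targets, indications, on-bits)."""

    entity_ids: tuple[str, ...]
    features: Mapping[str, frozenset]

    def __post_init__(self):
        object.__setattr__(self, "entity_ids", _unique_ids(self.entity_ids, "entity_ids"))
        known = set(self.entity_ids)
        feats = {}
        for e, toks in self.features.items():
            if e not in known:
                raise IdentifierError(f"feature entity {e!r} not in entity_ids")
            feats[e] = frozenset(toks)
        for e in self.entity_ids:
            if not feats.get(e):
                logger.warning("entity %r has an empty feature set", e)
                feats.setdefault(e, frozenset())
        object.__setattr__(self, "features", feats)


@dataclass(frozen=True)
class Hierarchy:
    """A code hierarchy (forest; multi-axial codes may have several parents).

    ``parent_edges`` maps each child code to its parent code(s);
    ``annotations`` maps each entity to a non-empty set of codes.  Path
    queries treat edges as undirected.
    """

    nodes: tuple[str, ...]
    parent_edges: Mapping[str, tuple[str, ...]]
    annotations: Mapping[str, frozenset]
    levels: Mapping[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        nodes = _unique_ids(self.nodes, "hierarchy nodes")
        object.__setattr__(self, "nodes", nodes)
        known = set(nodes)
        edges = {}
        dg = nx.DiGraph()
        dg.add_nodes_from(nodes)
        for child, parents in self.parent_edges.items():
            parents = tuple(parents) if not isinstance(parents, str) else (parents,)
            if child not in known:
                raise IdentifierError(f"hierarchy edge child {child!r} is not a node")
            for p in parents:
                if p not in known:
                    raise IdentifierError(f"hierarchy edge parent {p!r} is not a node")
                dg.add_edge(child, p)
            edges[child] = parents
        if not nx.is_directed_acyclic_graph(dg):
            raise ValidationError("hierarchy contains a cycle")
        object.__setattr__(self, "parent_edges", edges)
        anns = {}
        for e, codes in self.annotations.items():
            codes = frozenset(codes)
            if not codes:
                raise ValidationError(f"entity {e!r} has an empty annotation set")
            missing = codes - known
            if missing:
                raise IdentifierError(
                    f"entity {e!r} annotated with unknown code(s) {sorted(missing)}"
                )
            anns[e] = codes
        object.__setattr__(self, "annotations", anns)
        # depth = shortest distance to a root (node without parents)
        roots = [v for v in nodes if not edges.get(v)]
        und = dg.to_undirected(as_view=True)
        levels = {}
        for v in nodes:
            best = None
            for r in roots:
                try:
                    d = nx.shortest_path_length(und, v, r)
                except nx.NetworkXNoPath:
                    continue
                best = d if best is None else min(best, d)
            levels[v] = best if best is not None else 0
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "_graph", und)

    @property
    def graph(self) -> nx.Graph:
        """Undirected view of the hierarchy used for path queries."""
        return self._graph


def jaccard(set_u: AbstractSet, set_v: AbstractSet) -> float:
    """|U n V| / |U u V|; two empty sets give 0 by convention."""
    u, v = set(set_u), set(set_v)
    union = u | v
    if not union:
        logger.warning("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(u & v) / len(union)


def pairwise_jaccard(fs: FeatureSets, name: str = "jaccard") -> SimilarityGraph:
    """All-pairs Jaccard similarity graph over the entities of ``fs``."""
    if len(fs.entity_ids) < 2:
        raise ValidationError("pairwise similarity needs at least two entities")
    k = len(fs.entity_ids)
    a = np.zeros((k, k))
    sets = [fs.features[e] for e in fs.entity_ids]
    for i in range(k):
        for j in range(i + 1, k):
            a[i, j] = a[j, i] = jaccard(sets[i], sets[j])
    return SimilarityGraph(fs.entity_ids, a, name=name)


def set_shortest_path(codes_u: AbstractSet, codes_v: AbstractSet, h: Hierarchy) -> int:
    """Minimum undirected edge-count path between two annotation sets.

    Aggregates over all cross pairs of codes by the minimum; any shared
    code gives 0.
    """
    cu, cv = frozenset(codes_u), frozenset(codes_v)
    known = set(h.nodes)
    for c in cu | cv:
        if c not in known:
            raise IdentifierError(f"code {c!r} is not in the hierarchy")
    if cu & cv:
        return 0
    best = None
    for c in cu:
        dists = nx.single_source_shortest_path_length(h.graph, c)
        for d in cv:
            if d in dists and (best is None or dists[d] < best):
                best = dists[d]
    if best is None:
        raise DegenerateInputError(
            "annotation sets lie in disconnected parts of the hierarchy"
        )
    return int(best)


def taxonomy_similarity(
    h: Hierarchy,
    entity_ids: Sequence[str] | None = None,
    name: str = "taxonomy",
) -> SimilarityGraph:
    """Taxonomy similarity graph 1 - SP(u,v)/max over all annotated pairs.

    The normalizer is the empirical maximum of the set shortest path over
    all entity pairs; if it is 0 (every pair shares a code) the similarity
    is undefined and a degenerate-input error is raised.
    """
    ids = tuple(entity_ids) if entity_ids is not None else tuple(h.annotations)
    if len(ids) < 2:
        raise ValidationError("taxonomy similarity needs at least two annotated entities")
    for e in ids:
        if e not in h.annotations:
            raise IdentifierError(f"entity {e!r} has no hierarchy annotations")
    k = len(ids)
    sp = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = set_shortest_path(h.annotations[ids[i]], h.annotations[ids[j]], h)
            sp[i, j] = sp[j, i] = d
    norm = sp.max()
    if norm == 0:
        raise DegenerateInputError(
            "all entity pairs share a code (normalizer 0); a richer hierarchy is needed"
        )
    a = 1.0 - sp / norm
    np.fill_diagonal(a, 0.0)
    return SimilarityGraph(ids, a, name=name)
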