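"""Seed-reproducible synthetic fixtures with planted cluster structure.

The generator emulates the structure self-expressive models assume: drugs
and side effects fall into latent clusters, and a random bijection-like
compatibility map decides which drug cluster expresses which side-effect
cluster.  Inside a compatible block, associations appear with probability
``density_in``; elsewhere with ``density_out``.  Every drug is guaranteed at
least five positives (rows falling below the floor are redrawn), matching
the usual inclusion rule for clinical-trial datasets.  Cluster-consistent
similarity graphs and a balanced toy code hierarchy accompany the matrix so
every other module can be exercised without any database download.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AssociationMatrix, SimilarityGraph
from .exceptions import ValidationError
from .similarity import Hierarchy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block fixture (defaults: 60 x 50, 4 x 4 clusters)."""

    n_drugs: int = 60
    n_side_effects: int = 50
    n_drug_clusters: int = 4
    n_se_clusters: int = 4
    density_in: float = 0.6
    density_out: float = 0.02
    graph_p_in: float = 0.8
    graph_p_out: float = 0.05
    hierarchy_branching: int = 3
    hierarchy_depth: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 1 or self.n_side_effects < 1:
            raise ValidationError("entity counts must be positive")
        if not (1 <= self.n_drug_clusters <= self.n_drugs):
            raise ValidationError("n_drug_clusters must be in [1, n_drugs]")
        if not (1 <= self.n_se_clusters <= self.n_side_effects):
            raise ValidationError("n_se_clusters must be in [1, n_side_effects]")
        for p in (self.density_in, self.density_out, self.graph_p_in, self.graph_p_out):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.density_in <= self.density_out:
            raise ValidationError("density_in must exceed density_out")
        if self.hierarchy_branching < 2 or self.hierarchy_depth < 2:
            raise ValidationError("hierarchy needs branching >= 2 and depth >= 2")


MIN_POSITIVES_PER_DRUG = 5
_ROW_ATTEMPTS = 1000


def make_associations(
    spec: SyntheticSpec,
) -> tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """Block-structured binary association matrix with cluster labels.

    Returns the matrix plus the drug and side-effect cluster label arrays.
    Deterministic for a fixed spec (the seed lives in the spec).
    """
    if spec.n_side_effects < MIN_POSITIVES_PER_DRUG:
        raise ValidationError(
            f"cannot guarantee {MIN_POSITIVES_PER_DRUG} positives per drug with "
            f"only {spec.n_side_effects} side effects"
        )
    rng = np.random.default_rng(spec.seed)
    drug_labels = rng.integers(0, spec.n_drug_clusters, size=spec.n_drugs)
    se_labels = rng.integers(0, spec.n_se_clusters, size=spec.n_side_effects)
    # bijection-like compatibility: drug cluster c expresses se cluster perm[c mod K]
    perm = rng.permutation(spec.n_se_clusters)
    compat = perm[np.arange(spec.n_drug_clusters) % spec.n_se_clusters]

    probs = np.where(
        se_labels[np.newaxis, :] == compat[drug_labels][:, np.newaxis],
        spec.density_in,
        spec.density_out,
    )
    x = np.zeros((spec.n_drugs, spec.n_side_effects))
    for i in range(spec.n_drugs):
        for _ in range(_ROW_ATTEMPTS):
            row = (rng.random(spec.n_side_effects) < probs[i]).astype(float)
            if row.sum() >= MIN_POSITIVES_PER_DRUG:
                x[i] = row
                break
        else:
            raise ValidationError(
                f"drug row {i} could not reach {MIN_POSITIVES_PER_DRUG} positives "
                f"in {_ROW_ATTEMPTS} draws; densities are too low"
            )
    drug_ids = tuple(f"D{i:03d}" for i in range(spec.n_drugs))
    se_ids = tuple(f"S{j:03d}" for j in range(spec.n_side_effects))
    return AssociationMatrix(drug_ids, se_ids, x), drug_labels, se_labels


def make_cluster_graph(
    labels: Sequence[int],
    graph_p_in: float,
    graph_p_out: float,
    seed: int,
    entity_ids: Sequence[str] | None = None,
    name: str = "cluster",
) -> SimilarityGraph:
    """Unit-weight random graph with within/between-cluster edge probabilities."""
    labels = np.asarray(labels)
    k = len(labels)
    if k < 2:
        raise ValidationError("need at least two entities for a graph")
    rng = np.random.default_rng(seed)
    same = labels[:, np.newaxis] == labels[np.newaxis, :]
    p = np.where(same, graph_p_in, graph_p_out)
    draw = rng.random((k, k)) < p
    a = np.triu(draw, k=1).astype(float)
    a = a + a.T
    ids = tuple(entity_ids) if entity_ids is not None else tuple(f"E{i:03d}" for i in range(k))
    return SimilarityGraph(ids, a, name=name)


def make_toy_hierarchy(
    branching: int, depth: int, entities: Sequence[str], seed: int
) -> Hierarchy:
    """Balanced code tree of the given depth; entities annotated with 1-2 leaves.

    Leaf-to-leaf distances span 2 ... 2*depth (a depth-4 tree reproduces the
    2..8 shortest-path range of the 4-level ATC hierarchy).
    """
    if branching < 2 or depth < 2:
        raise ValidationError("hierarchy needs branching >= 2 and depth >= 2")
    rng = np.random.default_rng(seed)
    nodes: list[str] = []
    parent_edges: dict[str, tuple[str, ...]] = {}
    level_nodes: list[list[str]] = []
    for lvl in range(depth + 1):
        count = branching**lvl
        names = [f"L{lvl}.{i}" for i in range(count)]
        level_nodes.append(names)
        nodes.extend(names)
        if lvl > 0:
            for i, nm in enumerate(names):
                parent_edges[nm] = (level_nodes[lvl - 1][i // branching],)
    leaves = level_nodes[depth]
    annotations = {}
    for e in entities:
        n_codes = int(rng.integers(1, 3))
        chosen = rng.choice(len(leaves), size=n_codes, replace=False)
        annotations[e] = frozenset(leaves[c] for c in chosen)
    return Hierarchy(tuple(nodes), parent_edges, annotations)


def plant_holdout(
    X: AssociationMatrix, fraction: float, seed: int
) -> tuple[AssociationMatrix, tuple[tuple[int, int], ...]]:
    """Hide floor(fraction * P) random positives as recovery targets.

    A draw in which some row would lose all its positives is redrawn (up to
    100 times).  The hidden pairs and the masked matrix partition the
    original positives exactly.
    """
    if not (0 < fraction < 1):
        raise ValidationError("fraction must lie in (0, 1)")
    pos = np.argwhere(X.values == 1)
    n_hold = math.floor(fraction * len(pos))
    rng = np.random.default_rng(seed)
    if n_hold == 0:
        return X, ()
    for _ in range(100):
        chosen = rng.choice(len(pos), size=n_hold, replace=False)
        masked = X.values.copy()
        held = pos[chosen]
        masked[held[:, 0], held[:, 1]] = 0.0
        if (masked.sum(axis=1) >= 1).all():
            held_pairs = tuple(sorted((int(i), int(j)) for i, j in held))
            return (
                AssociationMatrix(X.drug_ids, X.side_effect_ids, masked),
                held_pairs,
            )
    raise ValidationError(
        "could not hold out the requested fraction without emptying a drug row"
    )
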