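"""Self-expressive matrix completion with graph regularization.

The model represents a binary drug x side-effect incidence matrix ``X``
(n drugs, m side effects) through two square non-negative coefficient
matrices: a drug self-representation ``H`` (n x n) with ``X ~= H X`` and a
side-effect self-representation ``W`` (m x m) with ``X ~= X W``.  Prediction
scores are the sum ``H X + X W``.  Each coefficient matrix is learned by
minimizing a convex objective

    1/2 ||X - X W||_F^2 + l2/2 ||W||_F^2 + l1 ||W||_1
        + sum_g  mu_g/2 * Tr(W L_g W^T) + gamma Tr(W),   W >= 0

(and the row-smoothed analogue for ``H`` with ``1/2 ||X - H X||_F^2``),
where ``L_g = D_g - A_g`` is the Laplacian of a side-information similarity
graph and ``gamma >> 0`` suppresses the trivial identity solution.  The
objective is minimized with multiplicative update rules that keep iterates
non-negative and never increase the objective; at convergence the iterate
satisfies the KKT complementarity conditions of the non-negativity
constrained problem, so the solution is a global optimum and is reproducible
across random initializations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    IdentifierError,
    NumericalError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: stabilizer added to every multiplicative-update denominator to avoid 0/0
DENOM_EPS = 1e-12
#: floor used in the relative-change convergence criterion
REL_EPS = 1e-12

Mode = Literal["W", "H"]


def _unique_ids(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(ids) == 0:
        raise ValidationError(f"{what}: identifier list is empty")
    if len(set(ids)) != len(ids):
        raise IdentifierError(f"{what}: duplicate identifiers")
    return ids


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary drug x side-effect incidence matrix with ordered identifiers."""

    drug_ids: tuple[str, ...]
    side_effect_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", _unique_ids(self.drug_ids, "drug_ids"))
        object.__setattr__(
            self, "side_effect_ids", _unique_ids(self.side_effect_ids, "side_effect_ids")
        )
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if vals.ndim != 2 or vals.shape != (len(self.drug_ids), len(self.side_effect_ids)):
            raise ValidationError(
                f"association matrix shape {vals.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.side_effect_ids)} side effects"
            )
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("association matrix entries must be exactly 0 or 1")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.drug_ids)

    @property
    def m(self) -> int:
        return len(self.side_effect_ids)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise IdentifierError(f"unknown drug identifier: {drug_id!r}") from None

    def side_effect_index(self, side_effect_id: str) -> int:
        try:
            return self.side_effect_ids.index(side_effect_id)
        except ValueError:
            raise IdentifierError(
                f"unknown side-effect identifier: {side_effect_id!r}"
            ) from None


@dataclass(frozen=True)
class SimilarityGraph:
    """Symmetric non-negative similarity graph over one entity set.

    The adjacency has a zero diagonal (self-edges carry no information for
    the Laplacian smoothness penalty).  ``degrees``, ``degree_matrix`` and
    ``laplacian`` expose the D and L = D - A views.
    """

    entity_ids: tuple[str, ...]
    adjacency: np.ndarray
    name: str = "graph"

    def __post_init__(self):
        object.__setattr__(self, "entity_ids", _unique_ids(self.entity_ids, "entity_ids"))
        a = np.asarray(self.adjacency, dtype=float)
        k = len(self.entity_ids)
        if a.shape != (k, k):
            raise ValidationError(f"adjacency shape {a.shape} does not match {k} entities")
        if not np.isfinite(a).all():
            raise ValidationError("adjacency contains non-finite weights")
        if a.min(initial=0.0) < 0:
            raise ValidationError("adjacency weights must be non-negative")
        if np.abs(a - a.T).max(initial=0.0) > 1e-10:
            raise ValidationError("adjacency is not symmetric (tolerance 1e-10)")
        if np.abs(np.diag(a)).max(initial=0.0) > 1e-12:
            raise ValidationError("adjacency diagonal must be zero")
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        object.__setattr__(self, "adjacency", a)

    @property
    def k(self) -> int:
        return len(self.entity_ids)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree_matrix - self.adjacency


@dataclass(frozen=True)
class GsemHyperparams:
    """Hyperparameters of one self-representation fit.

    l2/l1 are the elastic-net weights, ``graph_weights`` maps each similarity
    graph name to its smoothness weight, ``diag_penalty`` is the linear trace
    penalty gamma that suppresses the trivial identity solution, ``tol`` is
    the maximum relative per-element change used as stopping criterion and
    ``init_upper`` the upper bound of the uniform random initialization.
    """

    l2: float = 0.0
    l1: float = 0.0
    graph_weights: Mapping[str, float] = field(default_factory=dict)
    diag_penalty: float = 1e4
    tol: float = 1e-2
    max_iter: int = 500
    init_upper: float = 0.01
    seed: int = 0

    def __post_init__(self):
        scalars = {
            "l2": self.l2,
            "l1": self.l1,
            "diag_penalty": self.diag_penalty,
            "tol": self.tol,
            "init_upper": self.init_upper,
            **{f"graph_weights[{k}]": v for k, v in self.graph_weights.items()},
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")
        for name in ("l2", "l1", "diag_penalty"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for gname, w in self.graph_weights.items():
            if w < 0:
                raise ValidationError(f"graph weight for {gname!r} must be non-negative")
        if not (0 < self.tol < 1):
            raise ValidationError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")
        if self.init_upper <= 0:
            raise ValidationError("init_upper must be positive")
        object.__setattr__(self, "graph_weights", dict(self.graph_weights))


@dataclass(frozen=True)
class SelfRepresentation:
    """Learned square non-negative coefficient matrix over one entity set."""

    entity_ids: tuple[str, ...]
    matrix: np.ndarray
    role: Literal["drug", "side_effect"]

    def __post_init__(self):
        object.__setattr__(self, "entity_ids", _unique_ids(self.entity_ids, "entity_ids"))
        mat = np.asarray(self.matrix, dtype=float)
        k = len(self.entity_ids)
        if mat.shape != (k, k):
            raise ValidationError(f"matrix shape {mat.shape} does not match {k} entities")
        if not np.isfinite(mat).all():
            raise ValidationError("self-representation contains non-finite entries")
        if mat.min() < 0:
            raise ValidationError("self-representation entries must be non-negative")
        if self.role not in ("drug", "side_effect"):
            raise ValidationError(f"unknown role {self.role!r}")
        object.__setattr__(self, "matrix", mat)

    @property
    def k(self) -> int:
        return len(self.entity_ids)


@dataclass(frozen=True)
class FitTrace:
    """Per-iteration record of one multiplicative fit."""

    objective_per_iteration: tuple[float, ...]
    iterations: int
    converged: bool
    final_relative_change: float


@dataclass(frozen=True)
class ScoreMatrix:
    """Real non-negative prediction scores, same layout as the input matrix."""

    drug_ids: tuple[str, ...]
    side_effect_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.drug_ids), len(self.side_effect_ids)):
            raise ValidationError("score matrix shape does not match identifier lists")
        if not np.isfinite(s).all():
            raise ValidationError("scores contain non-finite entries")
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class ScoreExplanation:
    """Additive decomposition of one predicted score.

    ``drug_terms`` lists the drugs known to cause the side effect together
    with the learned drug-drug coefficient; ``se_terms`` lists the side
    effects known for the drug with the learned side-effect coefficient.
    Their sum equals the predicted score exactly.
    """

    drug_id: str
    side_effect_id: str
    drug_terms: tuple[tuple[str, float], ...]
    se_terms: tuple[tuple[str, float], ...]
    total: float


def build_graph(
    entity_ids: Sequence[str],
    weighted_edges: Sequence[tuple[str, str, float]],
    name: str = "graph",
) -> SimilarityGraph:
    """Assemble a :class:`SimilarityGraph` from an undirected weighted edge list.

    If both directions of an edge are given, the maximum of the two weights
    is kept.  Self-edges are dropped with a warning: they contribute nothing
    to the Laplacian penalty.
    """
    ids = _unique_ids(entity_ids, "entity_ids")
    index = {e: i for i, e in enumerate(ids)}
    a = np.zeros((len(ids), len(ids)))
    for u, v, w in weighted_edges:
        if u not in index:
            raise IdentifierError(f"graph {name!r}: unknown endpoint {u!r}")
        if v not in index:
            raise IdentifierError(f"graph {name!r}: unknown endpoint {v!r}")
        w = float(w)
        if not np.isfinite(w) or w <= 0:
            raise ValidationError(f"graph {name!r}: edge ({u},{v}) has invalid weight {w}")
        if u == v:
            logger.warning("graph %r: dropping self-edge on %r", name, u)
            continue
        i, j = index[u], index[v]
        w = max(w, a[i, j])
        a[i, j] = w
        a[j, i] = w
    return SimilarityGraph(ids, a, name=name)


def smoothness(
    S: np.ndarray, graph: SimilarityGraph, mode: Literal["columns", "rows"]
) -> float:
    """Laplacian smoothness penalty of a square coefficient matrix.

    ``columns`` mode returns Tr(S L S^T) — columns of S are the smoothed
    vectors (used for W); ``rows`` mode returns Tr(S^T L S) (used for H).
    """
    s = np.asarray(S, dtype=float)
    k = graph.k
    if s.shape != (k, k):
        raise ValidationError(
            f"matrix shape {s.shape} does not match graph {graph.name!r} with {k} nodes"
        )
    lap = graph.laplacian
    if mode == "columns":
        val = float(np.trace(s @ lap @ s.T))
    elif mode == "rows":
        val = float(np.trace(s.T @ lap @ s))
    else:
        raise ValidationError(f"unknown smoothness mode {mode!r}")
    return val


def _coerce_selfrep(S) -> np.ndarray:
    if isinstance(S, SelfRepresentation):
        return S.matrix
    return np.asarray(S, dtype=float)


def _check_instance(
    X: AssociationMatrix,
    S: np.ndarray,
    graphs: Sequence[SimilarityGraph],
    params: GsemHyperparams,
    mode: Mode,
) -> int:
    if mode == "W":
        k = X.m
    elif mode == "H":
        k = X.n
    else:
        raise ValidationError(f"unknown fit mode {mode!r}")
    if S.shape != (k, k):
        raise ValidationError(f"mode {mode}: coefficient matrix must be {k}x{k}, got {S.shape}")
    if np.isnan(S).any():
        raise ValidationError("coefficient matrix contains NaN")
    for g in graphs:
        if g.name not in params.graph_weights:
            raise ConfigurationError(f"no graph weight configured for graph {g.name!r}")
        if g.k != k:
            raise ValidationError(
                f"graph {g.name!r} has {g.k} nodes but mode {mode} needs {k}"
            )
    return k


def objective(
    X: AssociationMatrix,
    S,
    graphs: Sequence[SimilarityGraph],
    params: GsemHyperparams,
    mode: Mode,
) -> float:
    """Value of the convex self-expressive objective at S (W- or H-mode)."""
    s = _coerce_selfrep(S)
    _check_instance(X, s, graphs, params, mode)
    x = X.values
    if mode == "W":
        resid = x - x @ s
        smode = "columns"
    else:
        resid = x - s @ x
        smode = "rows"
    val = 0.5 * float(np.sum(resid * resid))
    val += 0.5 * params.l2 * float(np.sum(s * s))
    val += params.l1 * float(np.sum(np.abs(s)))
    for g in graphs:
        val += 0.5 * params.graph_weights[g.name] * smoothness(s, g, smode)
    val += params.diag_penalty * float(np.trace(s))
    return val


def _update_factors(
    s: np.ndarray,
    gram: np.ndarray,
    graph_terms: Sequence[tuple[float, np.ndarray, np.ndarray]],
    params: GsemHyperparams,
    mode: Mode,
) -> tuple[np.ndarray, np.ndarray]:
    """Numerator (negative gradient part) and denominator (positive part)."""
    if mode == "W":
        num = gram.copy()
        den = gram @ s
        for w, adj, deg in graph_terms:
            num += w * (s @ adj)
            den += w * (s * deg[np.newaxis, :])
    else:
        num = gram.copy()
        den = s @ gram
        for w, adj, deg in graph_terms:
            num += w * (adj @ s)
            den += w * (deg[:, np.newaxis] * s)
    den = den + params.l2 * s + params.l1
    den[np.diag_indices_from(den)] += params.diag_penalty
    return num, den


def _graph_terms(graphs, params):
    return [(params.graph_weights[g.name], g.adjacency, g.degrees) for g in graphs]


def multiplicative_step(
    S,
    X: AssociationMatrix,
    graphs: Sequence[SimilarityGraph],
    params: GsemHyperparams,
    mode: Mode,
) -> np.ndarray:
    """One multiplicative update of the coefficient matrix.

    Zeros are absorbing: an entry at exactly 0 stays 0 forever.  The update
    never increases the objective and preserves non-negativity; a stabilizer
    of 1e-12 is added to every denominator entry to avoid 0/0.
    """
    s = _coerce_selfrep(S)
    _check_instance(X, s, graphs, params, mode)
    x = X.values
    gram = x.T @ x if mode == "W" else x @ x.T
    num, den = _update_factors(s, gram, _graph_terms(graphs, params), params, mode)
    s_new = s * num / (den + DENOM_EPS)
    if not np.isfinite(s_new).all():
        raise NumericalError("multiplicative update produced non-finite entries")
    return s_new


def fit_selfrep(
    X: AssociationMatrix,
    graphs: Sequence[SimilarityGraph],
    params: GsemHyperparams,
    mode: Mode,
) -> tuple[SelfRepresentation, FitTrace]:
    """Learn one self-representation matrix by multiplicative descent.

    The matrix is initialized uniformly in (0, ``init_upper``) from
    ``params.seed`` and updated until the maximum relative per-element
    change drops below ``params.tol`` or ``max_iter`` is reached (in which
    case a warning is logged and ``converged`` is False).  The run is
    deterministic given the seed.
    """
    if mode == "W":
        k, ids, role = X.m, X.side_effect_ids, "side_effect"
        empty = np.flatnonzero(X.values.sum(axis=0) == 0)
        if empty.size:
            logger.warning(
                "%d side effect(s) have no associations; their coefficients decay to 0",
                empty.size,
            )
    else:
        k, ids, role = X.n, X.drug_ids, "drug"
        empty = np.flatnonzero(X.values.sum(axis=1) == 0)
        if empty.size:
            logger.warning(
                "%d drug(s) have no associations; their coefficients decay to 0",
                empty.size,
            )

    rng = np.random.default_rng(params.seed)
    s = rng.uniform(0.0, params.init_upper, size=(k, k))
    _check_instance(X, s, graphs, params, mode)

    x = X.values
    gram = x.T @ x if mode == "W" else x @ x.T
    gterms = _graph_terms(graphs, params)

    objs = [objective(X, s, graphs, params, mode)]
    converged = False
    rel = np.inf
    it = 0
    for it in range(1, params.max_iter + 1):
        num, den = _update_factors(s, gram, gterms, params, mode)
        s_new = s * num / (den + DENOM_EPS)
        if not np.isfinite(s_new).all():
            raise NumericalError(f"non-finite update at iteration {it} (mode {mode})")
        rel = float(np.max(np.abs(s_new - s) / (np.abs(s) + REL_EPS)))
        s = s_new
        objs.append(objective(X, s, graphs, params, mode))
        if rel < params.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "fit (mode %s) hit max_iter=%d without convergence (last rel change %.3g)",
            mode,
            params.max_iter,
            rel,
        )
    trace = FitTrace(tuple(objs), it, converged, rel)
    return SelfRepresentation(ids, s, role), trace


def kkt_residual(
    S,
    X: AssociationMatrix,
    graphs: Sequence[SimilarityGraph],
    params: GsemHyperparams,
    mode: Mode,
) -> float:
    """KKT complementarity residual max_ij |min(S_ij, grad_ij)|.

    Zero exactly at a KKT point of the non-negativity constrained problem:
    wherever S > 0 the gradient must vanish, and wherever S = 0 the gradient
    must be non-negative.
    """
    s = _coerce_selfrep(S)
    _check_instance(X, s, graphs, params, mode)
    if s.min() < 0:
        raise ValidationError("KKT residual is defined for non-negative S only")
    x = X.values
    gram = x.T @ x if mode == "W" else x @ x.T
    num, den = _update_factors(s, gram, _graph_terms(graphs, params), params, mode)
    grad = den - num
    return float(np.max(np.abs(np.minimum(s, grad))))


def fit_gsem(
    X: AssociationMatrix,
    drug_graphs: Sequence[SimilarityGraph],
    se_graphs: Sequence[SimilarityGraph],
    params_h: GsemHyperparams,
    params_w: GsemHyperparams,
) -> tuple[SelfRepresentation, SelfRepresentation, dict[str, FitTrace]]:
    """Fit the drug (H) and side-effect (W) self-representations.

    The two fits are independent, so the call order is irrelevant.  After
    convergence the (gamma-suppressed, already tiny) diagonals are hard
    zeroed so that predictions contain no self-loop contribution.
    """
    h, trace_h = fit_selfrep(X, drug_graphs, params_h, "H")
    w, trace_w = fit_selfrep(X, se_graphs, params_w, "W")
    hm = h.matrix.copy()
    wm = w.matrix.copy()
    np.fill_diagonal(hm, 0.0)
    np.fill_diagonal(wm, 0.0)
    h = replace(h, matrix=hm)
    w = replace(w, matrix=wm)
    return h, w, {"H": trace_h, "W": trace_w}


def predict(X: AssociationMatrix, H, W) -> ScoreMatrix:
    """Prediction scores H X + X W (entries at training ones are not masked)."""
    hm = _coerce_selfrep(H)
    wm = _coerce_selfrep(W)
    if hm.shape != (X.n, X.n):
        raise ValidationError(f"H must be {X.n}x{X.n}, got {hm.shape}")
    if wm.shape != (X.m, X.m):
        raise ValidationError(f"W must be {X.m}x{X.m}, got {wm.shape}")
    if isinstance(H, SelfRepresentation) and H.entity_ids != X.drug_ids:
        raise IdentifierError("H entity identifiers do not match the association matrix")
    if isinstance(W, SelfRepresentation) and W.entity_ids != X.side_effect_ids:
        raise IdentifierError("W entity identifiers do not match the association matrix")
    scores = hm @ X.values + X.values @ wm
    return ScoreMatrix(X.drug_ids, X.side_effect_ids, scores)


def explain_score(
    X: AssociationMatrix, H, W, drug_id: str, side_effect_id: str
) -> ScoreExplanation:
    """Decompose one predicted score into its additive evidence terms.

    The score for (drug i, side effect j) is the sum of H_iu over drugs u
    known to cause j plus W_vj over side effects v known for i.  Terms are
    sorted by descending contribution, ties broken by identifier order.
    """
    hm = _coerce_selfrep(H)
    wm = _coerce_selfrep(W)
    i = X.drug_index(drug_id)
    j = X.side_effect_index(side_effect_id)
    drugs_u = np.flatnonzero(X.values[:, j] == 1)
    ses_v = np.flatnonzero(X.values[i, :] == 1)
    drug_terms = sorted(
        ((X.drug_ids[u], float(hm[i, u])) for u in drugs_u),
        key=lambda t: (-t[1], X.drug_ids.index(t[0])),
    )
    se_terms = sorted(
        ((X.side_effect_ids[v], float(wm[v, j])) for v in ses_v),
        key=lambda t: (-t[1], X.side_effect_ids.index(t[0])),
    )
    total = float(hm[i, drugs_u].sum() + wm[ses_v, j].sum())
    return ScoreExplanation(drug_id, side_effect_id, tuple(drug_terms), tuple(se_terms), total)


def symmetrize(S) -> np.ndarray:
    """Symmetrized self-representation similarity (S + S^T) / 2."""
    s = _coerce_selfrep(S)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValidationError("symmetrize expects a square matrix")
    return (s + s.T) / 2.0
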