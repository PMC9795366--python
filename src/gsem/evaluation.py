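"""Evaluation protocol: splits, ranking metrics, RRF and shift statistics.

Link-prediction evaluation follows the standard held-out protocol for
bipartite association matrices: a fraction of the known positives is hidden
for testing, a fraction of the remainder for validation, and each positive
set is matched with seeded negatives sampled uniformly from the zero
entries (twice the number of positives by default).  Performance is
measured with AUROC (rank statistic with mid-rank tie handling) and AUPR
(step-wise precision-recall integral).

The ratio of reporting frequency (RRF) of a side effect is its drug count
divided by the maximum drug count over all side effects, a value in [0, 1]
used to contrast reporting prevalence between clinical-trial and
postmarketing data.  Distribution shifts across drug or side-effect groups
are assessed with one-tailed Wilcoxon rank-sum tests (both tails evaluated,
the more significant reported) under Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score
from statsmodels.stats.multitest import multipletests

from .core import (
    AssociationMatrix,
    GsemHyperparams,
    ScoreMatrix,
    SelfRepresentation,
    SimilarityGraph,
    fit_gsem,
    predict,
    symmetrize,
)
from .exceptions import (
    DegenerateInputError,
    IdentifierError,
    UndefinedMetricError,
    ValidationError,
)

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


@dataclass(frozen=True)
class EvaluationSplit:
    """Disjoint positive/negative index-pair sets for train/validation/test."""

    train_pos: frozenset[Pair]
    val_pos: frozenset[Pair]
    test_pos: frozenset[Pair]
    val_neg: frozenset[Pair]
    test_neg: frozenset[Pair]
    seed: int


@dataclass(frozen=True)
class RrfVector:
    """Per-side-effect ratio of reporting frequency with its normalizer Z."""

    side_effect_ids: tuple[str, ...]
    rrf: np.ndarray
    z: int

    def as_mapping(self) -> dict[str, float]:
        return {e: float(v) for e, v in zip(self.side_effect_ids, self.rrf)}


@dataclass(frozen=True)
class ShiftTestResult:
    """One group's rank-sum shift test against the pooled remainder."""

    group: str
    p_raw: float
    p_adjusted: float
    effect_size: float
    tail: Literal["greater", "less"]
    n: int
    significant: bool


def split_associations(
    X: AssociationMatrix,
    test_frac: float = 0.1,
    val_frac: float = 0.1,
    neg_ratio: int = 2,
    seed: int = 0,
) -> EvaluationSplit:
    """Seeded train/validation/test split of the positive entries.

    ``floor(test_frac * P)`` positives go to test, then
    ``floor(val_frac * (P - |test|))`` of the remainder to validation.
    Negatives (``neg_ratio`` per positive) are drawn uniformly without
    replacement from the zero entries, which by construction exclude every
    positive; validation and test negatives are disjoint.
    """
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValidationError("test_frac and val_frac must lie in (0, 1)")
    if neg_ratio < 1:
        raise ValidationError("neg_ratio must be at least 1")
    pos = np.argwhere(X.values == 1)
    p = len(pos)
    if p < 10:
        raise ValidationError(f"need at least 10 positives to split, got {p}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(p)
    n_test = math.floor(test_frac * p)
    n_val = math.floor(val_frac * (p - n_test))
    test_pos = pos[perm[:n_test]]
    val_pos = pos[perm[n_test : n_test + n_val]]
    train_pos = pos[perm[n_test + n_val :]]

    zeros = np.flatnonzero(X.values.ravel() == 0)
    want_test = neg_ratio * n_test
    want_val = neg_ratio * n_val
    if want_test + want_val > len(zeros):
        logger.warning(
            "requested %d negatives but only %d zero entries exist; sampling all",
            want_test + want_val,
            len(zeros),
        )
    take = min(want_test + want_val, len(zeros))
    chosen = rng.choice(zeros, size=take, replace=False)
    test_neg_flat = chosen[: min(want_test, take)]
    val_neg_flat = chosen[min(want_test, take) :]

    def pairs(idx2d: np.ndarray) -> frozenset[Pair]:
        return frozenset((int(i), int(j)) for i, j in idx2d)

    def flat_pairs(flat: np.ndarray) -> frozenset[Pair]:
        ii, jj = np.unravel_index(flat, X.values.shape)
        return frozenset((int(i), int(j)) for i, j in zip(ii, jj))

    return EvaluationSplit(
        train_pos=pairs(train_pos),
        val_pos=pairs(val_pos),
        test_pos=pairs(test_pos),
        val_neg=flat_pairs(val_neg_flat),
        test_neg=flat_pairs(test_neg_flat),
        seed=seed,
    )


def _check_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary")
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError("labels contain a single class; metric undefined")
    return s, y.astype(int)


def auroc(scores, labels) -> float:
    """AUROC via the rank statistic with mid-rank tie handling.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    s, y = _check_labels(scores, labels)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def aupr(scores, labels) -> float:
    """AUPR as the step-wise precision-recall integral with ties grouped."""
    s, y = _check_labels(scores, labels)
    return float(average_precision_score(y, s))


def rrf(X: AssociationMatrix) -> RrfVector:
    """Ratio of reporting frequency per side effect: column count / Z."""
    counts = X.values.sum(axis=0)
    z = counts.max()
    if z == 0:
        raise DegenerateInputError("association matrix has no positives; RRF undefined")
    return RrfVector(X.side_effect_ids, counts / z, int(z))


def per_entity_auroc(
    scores: ScoreMatrix | np.ndarray,
    X_train: AssociationMatrix,
    test_positives: Iterable[Pair],
    axis: Literal["drug", "side_effect"] = "drug",
    min_test: int = 10,
) -> dict[str, float]:
    """Per-drug (or per-side-effect) AUROC over that entity's training zeros.

    For each entity with at least ``min_test`` test positives, candidates
    are its training-zero entries, labelled 1 at test positives and 0
    elsewhere.  Entities below the threshold are omitted.
    """
    s = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    if s.shape != X_train.values.shape:
        raise ValidationError("score matrix shape does not match the training matrix")
    mask = np.zeros_like(X_train.values, dtype=bool)
    for i, j in test_positives:
        if X_train.values[i, j] != 0:
            raise ValidationError(f"test positive ({i},{j}) is a training positive")
        mask[i, j] = True
    out: dict[str, float] = {}
    if axis == "drug":
        for i, ent in enumerate(X_train.drug_ids):
            cand = X_train.values[i] == 0
            y = mask[i][cand]
            if int(y.sum()) >= min_test and y.sum() < len(y):
                out[ent] = auroc(s[i][cand], y.astype(int))
    elif axis == "side_effect":
        for j, ent in enumerate(X_train.side_effect_ids):
            cand = X_train.values[:, j] == 0
            y = mask[:, j][cand]
            if int(y.sum()) >= min_test and y.sum() < len(y):
                out[ent] = auroc(s[:, j][cand], y.astype(int))
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    return out


def group_metrics(
    per_entity_values: Mapping[str, float], grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Mean/median/count of per-entity values by group label.

    Entities without a group label are collected under ``unclassified``.
    """
    rows = [
        (grouping.get(e, "unclassified"), v) for e, v in per_entity_values.items()
    ]
    if not rows:
        raise ValidationError("no per-entity values to summarize")
    df = pd.DataFrame(rows, columns=["group", "value"])
    out = df.groupby("group")["value"].agg(mean="mean", median="median", n="size")
    out["n"] = out["n"].astype(int)
    return out.sort_index()


def _ranksum_onesided(group: np.ndarray, rest: np.ndarray, alternative: str) -> float:
    """One-tailed Wilcoxon rank-sum p-value.

    Exact null distribution when both sides have fewer than 10 observations
    and no ties are present; normal approximation with tie correction
    otherwise.
    """
    exact = len(group) < 10 and len(rest) < 10
    pooled = np.concatenate([group, rest])
    if exact and len(np.unique(pooled)) == len(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(group, rest, alternative=alternative, method=method)
    return float(res.pvalue)


def rrf_shift_test(
    values: Mapping[str, float],
    membership: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    min_group: int = 3,
) -> list[ShiftTestResult]:
    """Rank-sum shift of each group's values against the pooled remainder.

    Both one-tailed alternatives are evaluated and the more significant is
    reported with its direction; p-values are Benjamini-Hochberg adjusted
    across the tested groups.  Effect size is the group median minus the
    overall median.  Groups with fewer than ``min_group`` members are
    skipped with a warning.
    """
    if len(membership) < 2:
        raise ValidationError("need at least two groups for a shift analysis")
    all_vals = np.array(list(values.values()), dtype=float)
    overall_median = float(np.median(all_vals))
    tested: list[tuple[str, float, str, float, int]] = []
    for gname in sorted(membership):
        members = [e for e in membership[gname] if e in values]
        if len(members) < min_group:
            logger.warning("group %r has n=%d < %d; skipped", gname, len(members), min_group)
            continue
        member_set = set(members)
        g = np.array([values[e] for e in members], dtype=float)
        rest = np.array([v for e, v in values.items() if e not in member_set], dtype=float)
        if len(rest) == 0:
            logger.warning("group %r covers all entities; skipped", gname)
            continue
        p_greater = _ranksum_onesided(g, rest, "greater")
        p_less = _ranksum_onesided(g, rest, "less")
        if p_greater <= p_less:
            p, tail = p_greater, "greater"
        else:
            p, tail = p_less, "less"
        effect = float(np.median(g)) - overall_median
        tested.append((gname, p, tail, effect, len(g)))
    if not tested:
        return []
    raw = [t[1] for t in tested]
    reject, p_adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    return [
        ShiftTestResult(
            group=name,
            p_raw=p,
            p_adjusted=float(pa),
            effect_size=eff,
            tail=tail,  # type: ignore[arg-type]
            n=n,
            significant=bool(rej),
        )
        for (name, p, tail, eff, n), pa, rej in zip(tested, p_adj, reject)
    ]


def _subset_graph(graph: SimilarityGraph, keep: np.ndarray) -> SimilarityGraph:
    ids = tuple(graph.entity_ids[i] for i in keep)
    return SimilarityGraph(ids, graph.adjacency[np.ix_(keep, keep)], name=graph.name)


def integration_eval(
    target_drug: str,
    X_clinical: AssociationMatrix,
    X_post: AssociationMatrix,
    strategy: Literal[1, 2],
    chem_graph: SimilarityGraph,
    params_h: GsemHyperparams,
    params_w: GsemHyperparams,
    leak_threshold: float = 0.6,
    drug_graphs: Sequence[SimilarityGraph] = (),
    se_graphs: Sequence[SimilarityGraph] = (),
) -> float:
    """Per-drug AUROC for postmarket recovery under a data-integration strategy.

    The target drug keeps only its clinical-trial associations in training.
    The other drugs contribute clinical associations (strategy 1) or
    clinical plus postmarket associations (strategy 2).  Any other drug with
    chemical similarity to the target at or above ``leak_threshold`` is
    removed to prevent leakage through close analogs.  The model is fitted
    with the caller's fixed hyperparameters and scored on the target's
    training-zero entries, its postmarket associations as positives.
    """
    if strategy not in (1, 2):
        raise ValidationError(f"strategy must be 1 or 2, got {strategy}")
    if X_clinical.drug_ids != X_post.drug_ids or (
        X_clinical.side_effect_ids != X_post.side_effect_ids
    ):
        raise IdentifierError("clinical and postmarket matrices must share identifiers")
    if chem_graph.entity_ids != X_clinical.drug_ids:
        raise IdentifierError("chemical graph entities must match the drug identifiers")
    t = X_clinical.drug_index(target_drug)
    if X_clinical.values[t].sum() < 1:
        raise ValidationError(f"target {target_drug!r} has no clinical positives")
    if X_post.values[t].sum() < 1:
        raise ValidationError(f"target {target_drug!r} has no postmarket positives")

    sims = chem_graph.adjacency[t]
    keep = [u for u in range(X_clinical.n) if u == t or sims[u] < leak_threshold]
    if len(keep) == 1:
        raise DegenerateInputError(
            "every other drug was removed by the chemical-leakage filter"
        )
    keep = np.array(keep)
    removed = X_clinical.n - len(keep)
    if removed:
        logger.info("leak filter removed %d drug(s) similar to %r", removed, target_drug)

    train = X_clinical.values[keep].copy()
    t_new = int(np.flatnonzero(keep == t)[0])
    if strategy == 2:
        post_rows = X_post.values[keep]
        others = np.arange(len(keep)) != t_new
        train[others] = np.maximum(train[others], post_rows[others])
    X_train = AssociationMatrix(
        tuple(X_clinical.drug_ids[i] for i in keep), X_clinical.side_effect_ids, train
    )
    dgraphs = [_subset_graph(g, keep) for g in drug_graphs]
    h, w, _ = fit_gsem(X_train, dgraphs, list(se_graphs), params_h, params_w)
    scores = predict(X_train, h, w).scores

    cand = train[t_new] == 0
    y = (X_post.values[t] == 1)[cand].astype(int)
    return auroc(scores[t_new][cand], y)


DEFAULT_BIN_EDGES = (0.0, 0.05, 0.1, 0.2, np.inf)


def selfrep_similarity_bins(
    sym_selfrep: np.ndarray | SelfRepresentation,
    side_info_graph: SimilarityGraph | np.ndarray,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Distribution of side-information similarity, binned by learned similarity.

    Each off-diagonal pair is assigned to a bin by its symmetrized
    self-representation similarity (intervals closed on the left, open on
    the right, last bin open-ended); per bin the mean, median, quartiles and
    count of the side-information similarity are reported.  Empty bins are
    reported with n=0.
    """
    m = symmetrize(sym_selfrep)
    side = (
        side_info_graph.adjacency
        if isinstance(side_info_graph, SimilarityGraph)
        else np.asarray(side_info_graph, dtype=float)
    )
    if side.shape != m.shape:
        raise ValidationError("self-representation and side-information sizes differ")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 3 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be strictly increasing with >= 2 bins")
    iu = np.triu_indices(m.shape[0], k=1)
    sv = m[iu]
    info = side[iu]
    inner = edges[1:-1]
    idx = np.searchsorted(inner, sv, side="right")
    labels = []
    for b in range(len(edges) - 1):
        hi = edges[b + 1]
        labels.append(f"[{edges[b]:g}, {hi:g})" if np.isfinite(hi) else f">= {edges[b]:g}")
    rows = []
    for b, label in enumerate(labels):
        vals = info[idx == b]
        if vals.size:
            rows.append(
                {
                    "bin": label,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                }
            )
        else:
            rows.append(
                {"bin": label, "n": 0, "mean": np.nan, "median": np.nan, "q25": np.nan, "q75": np.nan}
            )
    return pd.DataFrame(rows).set_index("bin")
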