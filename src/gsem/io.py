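"""Readers and writers for the package's plain-text formats.

All formats are UTF-8 tab-separated text:

* associations — ``drug_id  side_effect_id  label`` with a header row; one
  association per row, the label recording provenance (``clinical``,
  ``sider_post``, ``offsides_post``);
* graphs — undirected edge lists ``entity_a  entity_b  weight`` with a
  header row, each edge written once;
* matrices — dense tables with row/column identifier headers, values
  printed at 17 significant digits so a write/read round trip is bit exact;
* hierarchies — ``child_code  parent_code`` edge lists plus a separate
  ``entity_id  leaf_code`` annotation file;
* features — ``entity_id  token``, one token per row;
* config — flat ``key = value`` lines with dotted sections (``h.``, ``w.``,
  ``eval.``).

Writers emit ``#``-prefixed header comments (tool version, seed when known);
readers skip them, so outputs are closed under round trip.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .core import AssociationMatrix, GsemHyperparams, SimilarityGraph, build_graph
from .exceptions import ParseError, ValidationError
from .similarity import FeatureSets, Hierarchy

logger = logging.getLogger(__name__)

ASSOCIATION_LABELS = ("clinical", "sider_post", "offsides_post")


def _read_rows(path, n_fields: int, header: Sequence[str] | None):
    """Yield (line_number, fields) from a TSV, validating the field count."""
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        lineno = 0
        expect_header = header is not None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if expect_header:
                if [f.strip() for f in fields] != list(header):
                    raise ParseError(
                        f"expected header {list(header)}, got {fields}", line=lineno
                    )
                expect_header = False
                continue
            if len(fields) != n_fields:
                raise ParseError(
                    f"expected {n_fields} tab-separated fields, got {len(fields)}",
                    line=lineno,
                )
            rows.append((lineno, fields))
        if expect_header:
            raise ValidationError(f"{path}: empty file (missing header)")
    return rows


def _header_comment(seed: int | None = None) -> str:
    line = f"# gsem v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _id_directive(key: str, ids: Sequence[str]) -> str:
    # identifier order is not recoverable from a long-format body alone,
    # so writers record it in a comment directive that readers honor
    return f"#{key}=" + "\t".join(ids) + "\n"


def _scan_directives(path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#") and "=" in line and not line.startswith("# "):
                key, _, rest = line[1:].partition("=")
                out[key] = tuple(rest.split("\t")) if rest else ()
    return out


def read_associations(
    path,
    label_filter: str | Sequence[str] | None = None,
    min_se_per_drug: int = 0,
) -> AssociationMatrix:
    """Read a long-format association table into a binary matrix.

    Identifier order follows first appearance.  Duplicate rows are collapsed
    with a warning; drugs with fewer than ``min_se_per_drug`` associations
    (after label filtering) are dropped with a logged count.
    """
    rows = _read_rows(path, 3, header=("drug_id", "side_effect_id", "label"))
    if label_filter is None:
        wanted = None
    elif isinstance(label_filter, str):
        wanted = {label_filter}
    else:
        wanted = set(label_filter)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dup = 0
    for lineno, (d, s, lab) in rows:
        d, s, lab = d.strip(), s.strip(), lab.strip()
        if not d or not s or not lab:
            raise ParseError("empty field in association row", line=lineno)
        if wanted is not None and lab not in wanted:
            continue
        if (d, s) in seen:
            dup += 1
            continue
        seen.add((d, s))
        pairs.append((d, s))
    if dup:
        logger.warning("collapsed %d duplicate association row(s)", dup)
    if not pairs:
        raise ValidationError(f"{path}: no associations after filtering")
    if min_se_per_drug > 0:
        counts: dict[str, int] = defaultdict(int)
        for d, _ in pairs:
            counts[d] += 1
        kept = {d for d, c in counts.items() if c >= min_se_per_drug}
        dropped = len(counts) - len(kept)
        if dropped:
            logger.info(
                "dropped %d drug(s) with fewer than %d associations", dropped, min_se_per_drug
            )
        pairs = [(d, s) for d, s in pairs if d in kept]
        if not pairs:
            raise ValidationError(f"{path}: every drug fell below min_se_per_drug")
    drug_ids: list[str] = []
    se_ids: list[str] = []
    d_idx: dict[str, int] = {}
    s_idx: dict[str, int] = {}
    for d, s in pairs:
        if d not in d_idx:
            d_idx[d] = len(drug_ids)
            drug_ids.append(d)
        if s not in s_idx:
            s_idx[s] = len(se_ids)
            se_ids.append(s)
    directives = _scan_directives(path)
    for key, ids, idx in (("drugs", drug_ids, d_idx), ("side_effects", se_ids, s_idx)):
        declared = directives.get(key)
        if declared and set(declared) >= set(ids):
            ids[:] = [e for e in declared if e in idx]
            for pos, e in enumerate(ids):
                idx[e] = pos
    x = np.zeros((len(drug_ids), len(se_ids)))
    for d, s in pairs:
        x[d_idx[d], s_idx[s]] = 1.0
    return AssociationMatrix(tuple(drug_ids), tuple(se_ids), x)


def write_associations(
    X: AssociationMatrix, path, label: str = "clinical", seed: int | None = None
) -> None:
    """Write the positives of a matrix as a long-format association table."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        fh.write(_id_directive("drugs", X.drug_ids))
        fh.write(_id_directive("side_effects", X.side_effect_ids))
        fh.write("drug_id\tside_effect_id\tlabel\n")
        for i, j in np.argwhere(X.values == 1):
            fh.write(f"{X.drug_ids[i]}\t{X.side_effect_ids[j]}\t{label}\n")


def read_graph(path, name: str | None = None) -> SimilarityGraph:
    """Read an undirected weighted edge list into a similarity graph.

    An edge listed in both directions with differing weights is rejected
    (files written by this package list each edge once).
    """
    rows = _read_rows(path, 3, header=("entity_a", "entity_b", "weight"))
    edges: list[tuple[str, str, float]] = []
    seen: dict[tuple[str, str], float] = {}
    ids: list[str] = []
    known: set[str] = set()
    for lineno, (a, b, w) in rows:
        a, b = a.strip(), b.strip()
        try:
            wv = float(w)
        except ValueError:
            raise ParseError(f"invalid weight {w!r}", line=lineno) from None
        key = (min(a, b), max(a, b))
        if key in seen and seen[key] != wv:
            raise ValidationError(
                f"{path}: asymmetric duplicate edge {a}-{b} "
                f"({seen[key]} vs {wv})"
            )
        seen[key] = wv
        edges.append((a, b, wv))
        for e in (a, b):
            if e not in known:
                known.add(e)
                ids.append(e)
    declared = _scan_directives(path).get("entities")
    if declared and set(declared) >= known:
        ids = list(declared)  # preserves writer order and isolated nodes
    return build_graph(ids, edges, name=name or Path(path).stem)


def write_graph(graph: SimilarityGraph, path, seed: int | None = None) -> None:
    """Write a similarity graph as an edge list (upper triangle, one row per edge)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        fh.write(_id_directive("entities", graph.entity_ids))
        fh.write("entity_a\tentity_b\tweight\n")
        k = graph.k
        for i in range(k):
            for j in range(i + 1, k):
                w = graph.adjacency[i, j]
                if w > 0:
                    fh.write(f"{graph.entity_ids[i]}\t{graph.entity_ids[j]}\t{w:.17g}\n")


def write_matrix(
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    values: np.ndarray,
    path,
    seed: int | None = None,
) -> None:
    """Write a dense matrix as TSV with identifier headers (17 significant digits)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValidationError("matrix shape does not match identifier lists")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        fh.write("\t".join(["id", *col_ids]) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Read a dense TSV matrix; round-trips :func:`write_matrix` bit exactly."""
    path = Path(path)
    row_ids: list[str] = []
    col_ids: list[str] | None = None
    data: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if col_ids is None:
                if fields[0] != "id":
                    raise ParseError("matrix header must start with 'id'", line=lineno)
                col_ids = fields[1:]
                continue
            if len(fields) != len(col_ids) + 1:
                raise ParseError(
                    f"expected {len(col_ids) + 1} fields, got {len(fields)}", line=lineno
                )
            row_ids.append(fields[0])
            try:
                data.append([float(v) for v in fields[1:]])
            except ValueError:
                raise ParseError("invalid numeric value", line=lineno) from None
    if col_ids is None:
        raise ValidationError(f"{path}: empty matrix file")
    return tuple(row_ids), tuple(col_ids), np.array(data)


def read_hierarchy(edges_path, annotations_path) -> Hierarchy:
    """Read ``child parent`` edges and ``entity leaf_code`` annotations."""
    erows = _read_rows(edges_path, 2, header=("child_code", "parent_code"))
    parent_edges: dict[str, list[str]] = defaultdict(list)
    nodes: list[str] = []
    known: set[str] = set()
    for _, (c, p) in erows:
        c, p = c.strip(), p.strip()
        for v in (c, p):
            if v not in known:
                known.add(v)
                nodes.append(v)
        if p not in parent_edges[c]:
            parent_edges[c].append(p)
    arows = _read_rows(annotations_path, 2, header=("entity_id", "leaf_code"))
    annotations: dict[str, set[str]] = defaultdict(set)
    for _, (e, code) in arows:
        annotations[e.strip()].add(code.strip())
    return Hierarchy(
        tuple(nodes),
        {c: tuple(ps) for c, ps in parent_edges.items()},
        {e: frozenset(cs) for e, cs in annotations.items()},
    )


def write_hierarchy(h: Hierarchy, edges_path, annotations_path) -> None:
    with Path(edges_path).open("w", encoding="utf-8") as fh:
        fh.write(_header_comment())
        fh.write("child_code\tparent_code\n")
        for child in h.nodes:
            for parent in h.parent_edges.get(child, ()):
                fh.write(f"{child}\t{parent}\n")
    with Path(annotations_path).open("w", encoding="utf-8") as fh:
        fh.write(_header_comment())
        fh.write("entity_id\tleaf_code\n")
        for e in sorted(h.annotations):
            for code in sorted(h.annotations[e]):
                fh.write(f"{e}\t{code}\n")


def read_features(path) -> FeatureSets:
    """Read ``entity token`` rows into feature sets (order of first appearance)."""
    rows = _read_rows(path, 2, header=("entity_id", "token"))
    feats: dict[str, set[str]] = defaultdict(set)
    ids: list[str] = []
    for _, (e, tok) in rows:
        e = e.strip()
        if e not in feats:
            ids.append(e)
        feats[e].add(tok.strip())
    if not ids:
        raise ValidationError(f"{path}: no feature rows")
    return FeatureSets(tuple(ids), {e: frozenset(s) for e, s in feats.items()})


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration: one hyperparameter block per fit plus evaluation knobs."""

    params_h: GsemHyperparams = field(default_factory=GsemHyperparams)
    params_w: GsemHyperparams = field(default_factory=GsemHyperparams)
    test_frac: float = 0.1
    val_frac: float = 0.1
    neg_ratio: int = 2
    min_test: int = 10
    leak_threshold: float = 0.6


_HP_FLOAT = {"l2", "l1", "diag_penalty", "tol", "init_upper"}
_HP_INT = {"max_iter", "seed"}


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config.

    Keys are dotted: ``h.l2``, ``w.tol``, ``h.graph.chem`` (a smoothness
    weight for the drug graph named ``chem``), ``eval.test_frac`` ...
    Unknown keys raise a validation error.
    """
    path = Path(path)
    blocks: dict[str, dict] = {"h": {"graph_weights": {}}, "w": {"graph_weights": {}}}
    ev: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError("expected 'key = value'", line=lineno)
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            parts = key.split(".")
            if parts[0] in ("h", "w"):
                if len(parts) == 3 and parts[1] == "graph":
                    blocks[parts[0]]["graph_weights"][parts[2]] = float(value)
                elif len(parts) == 2 and parts[1] in _HP_FLOAT:
                    blocks[parts[0]][parts[1]] = float(value)
                elif len(parts) == 2 and parts[1] in _HP_INT:
                    blocks[parts[0]][parts[1]] = int(value)
                else:
                    raise ParseError(f"unknown config key {key!r}", line=lineno)
            elif parts[0] == "eval" and len(parts) == 2:
                if parts[1] in ("test_frac", "val_frac", "leak_threshold"):
                    ev[parts[1]] = float(value)
                elif parts[1] in ("neg_ratio", "min_test"):
                    ev[parts[1]] = int(value)
                else:
                    raise ParseError(f"unknown config key {key!r}", line=lineno)
            else:
                raise ParseError(f"unknown config key {key!r}", line=lineno)
    return RunConfig(
        params_h=GsemHyperparams(**blocks["h"]),
        params_w=GsemHyperparams(**blocks["w"]),
        **ev,
    )
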