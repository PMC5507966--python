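"""Coexpression network inference from an expression matrix.

Pipeline: score all gene pairs with one association measure
(:func:`pairwise_association`), rank the pairs (:func:`rank_edges`), keep a
top fraction as the inferred network (:func:`select_top_fraction`, the
"top 5%" convention), and optionally orient edges with a transcription
factor list (:func:`orient_with_tfs`): a TF--non-TF edge becomes TF->target,
a TF--TF edge is kept in both directions, and a non-TF--non-TF edge stays
undirected.

Signed measures (Pearson, Spearman, ...) are ranked by absolute score by
default, so strong inhibition is retained alongside strong activation; this
is configurable.  Pairs on which a measure raises a degenerate-input error
are recorded as NaN sentinels, excluded from ranking, and counted, so they
never enter a ROC as genuine low scores.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import measures as _measures
from .errors import (
    AssocnetError,
    DegenerateInputError,
    ParameterError,
    SampleSizeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "AssociationMatrix",
    "Edge",
    "EdgeList",
    "pairwise_association",
    "rank_edges",
    "select_top_fraction",
    "orient_with_tfs",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """The m x n expression matrix G: m genes (rows) by n samples (columns)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        m, n = len(self.gene_ids), len(self.sample_ids)
        if vals.shape != (m, n):
            raise ParameterError(
                f"values shape {vals.shape} != ({m} genes, {n} samples)"
            )
        if len(set(self.gene_ids)) != m:
            raise ParameterError("duplicate gene ids")
        if m < 2 or n < 2:
            raise SampleSizeError("need at least 2 genes and 2 samples")
        if not np.isfinite(vals).all():
            raise DegenerateInputError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric m x m matrix of one measure's pair scores.

    The diagonal and any skipped (degenerate) pairs hold NaN sentinels,
    which downstream ranking excludes.
    """

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    measure_id: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    n_skipped: int = 0


@dataclass(frozen=True)
class Edge:
    gene_a: str
    gene_b: str
    score: float
    rank: int
    direction: str = "--"  # one of "--", "->", "<->"


@dataclass(frozen=True)
class EdgeList:
    edges: tuple[Edge, ...]
    directed: bool = False
    orientation_source: str = "none"  # "none" or "tf_list"
    ranked_by_absolute: bool = True


def pairwise_association(
    expr: ExpressionMatrix,
    measure_id: str,
    params: dict | None = None,
    seed: int | None = None,
) -> AssociationMatrix:
    """Score all m(m-1)/2 gene pairs of an expression matrix with one measure.

    Degenerate pairs are skipped (NaN sentinel) and logged; the call is
    deterministic for a fixed (input, measure, params, seed).
    """
    if measure_id not in _measures.REGISTRY:
        raise ParameterError(
            f"unknown measure {measure_id!r}; known: "
            + ", ".join(_measures.REGISTRY)
        )
    m = expr.n_genes
    scores = np.full((m, m), np.nan)
    skipped = 0
    for i in range(m):
        for j in range(i + 1, m):
            try:
                mv = _measures.compute(
                    measure_id, expr.values[i], expr.values[j], params, seed
                )
                scores[i, j] = scores[j, i] = mv.value
            except (DegenerateInputError, SampleSizeError) as exc:
                skipped += 1
                logger.info(
                    "skipping pair (%s, %s) for %s: %s",
                    expr.gene_ids[i], expr.gene_ids[j], measure_id, exc,
                )
    return AssociationMatrix(
        gene_ids=expr.gene_ids,
        scores=scores,
        measure_id=measure_id,
        params=dict(params or {}),
        seed=seed if _measures.REGISTRY[measure_id].stochastic else None,
        n_skipped=skipped,
    )


def rank_edges(
    assoc: AssociationMatrix, use_absolute: bool | None = None
) -> EdgeList:
    """Rank all scored pairs into an edge list.

    Sorts descending by |score| (default for signed measures, per the
    registry) or by the raw score; ties break by lexicographic gene-pair
    order so rankings are reproducible.  Skipped (NaN) pairs are omitted.
    """
    if use_absolute is None:
        info = _measures.REGISTRY.get(assoc.measure_id)
        use_absolute = info.signed if info is not None else True
    m = len(assoc.gene_ids)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            s = assoc.scores[i, j]
            if np.isnan(s):
                continue
            a, b = sorted((assoc.gene_ids[i], assoc.gene_ids[j]))
            rows.append((a, b, float(s)))
    if not rows:
        raise AssocnetError("no finite scores to rank (all pairs skipped)")
    key = (lambda r: (-abs(r[2]), r[0], r[1])) if use_absolute else (
        lambda r: (-r[2], r[0], r[1])
    )
    rows.sort(key=key)
    edges = tuple(
        Edge(gene_a=a, gene_b=b, score=s, rank=idx + 1)
        for idx, (a, b, s) in enumerate(rows)
    )
    return EdgeList(edges=edges, ranked_by_absolute=bool(use_absolute))


def select_top_fraction(edges: EdgeList, fraction: float) -> EdgeList:
    """Keep the first ceil(fraction * E) edges of a ranked list."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    if not edges.edges:
        raise AssocnetError("empty edge list")
    keep = math.ceil(fraction * len(edges.edges))
    return replace(edges, edges=edges.edges[:keep])


def orient_with_tfs(
    edges: EdgeList, tfs: set[str], universe: set[str] | None = None
) -> EdgeList:
    """Orient edges with a transcription-factor list.

    TF--non-TF becomes TF->target, TF--TF keeps both directions ("<->"),
    non-TF--non-TF stays undirected ("--").  TF ids absent from the gene
    universe (the genes present in the edge list, unless a wider `universe`
    is given) produce a warning, not an error.  The set of unordered gene
    pairs is unchanged.
    """
    tfs = set(tfs)
    if not tfs:
        return replace(edges, directed=False, orientation_source="none")
    if universe is None:
        universe = {g for e in edges.edges for g in (e.gene_a, e.gene_b)}
    unknown = tfs - set(universe)
    if unknown:
        warnings.warn(
            f"{len(unknown)} TF id(s) absent from the network genes: "
            + ", ".join(sorted(unknown)[:5]),
            stacklevel=2,
        )
    oriented = []
    for e in edges.edges:
        a_tf, b_tf = e.gene_a in tfs, e.gene_b in tfs
        if a_tf and b_tf:
            oriented.append(replace(e, direction="<->"))
        elif a_tf:
            oriented.append(replace(e, direction="->"))
        elif b_tf:
            # store regulator first for directed edges
            oriented.append(
                Edge(e.gene_b, e.gene_a, e.score, e.rank, direction="->")
            )
        else:
            oriented.append(replace(e, direction="--"))
    return EdgeList(
        edges=tuple(oriented),
        directed=True,
        orientation_source="tf_list",
        ranked_by_absolute=edges.ranked_by_absolute,
    )
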