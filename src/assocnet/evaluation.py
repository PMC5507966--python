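"""Scoring inferred networks against a gold standard.

Follows the DREAM-style protocol: regulatory directions are omitted, so a
gold standard of directed regulator->target edges is collapsed to unordered
gene pairs, an inferred edge selection is compared against those labels, and
sensitivity (SN), specificity (SP), accuracy (ACC), F-measure, Matthews
correlation coefficient (MCC) and the area under the ROC curve (AUC) are
reported.

The ROC sweep walks the ranked edge list one distinct score at a time; tie
groups contribute a single diagonal segment, so the trapezoidal AUC equals
the tie-corrected Mann-Whitney statistic.  Pairs missing from the edge list
(e.g. degenerate pairs skipped upstream) are placed in a final sentinel tie
group below every scored pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

from .errors import UndefinedMetricError, UniverseMismatchError
from .netinfer import EdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "ConfusionCounts",
    "MetricSet",
    "collapse_undirected",
    "confusion_at_selection",
    "point_metrics",
    "roc_auc",
]

Pair = tuple[str, str]


def _canon(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GoldStandard:
    """Known true directed regulations over a gene universe."""

    universe: frozenset[str]
    positives: frozenset[Pair]  # directed (regulator, target) pairs

    def __post_init__(self):
        for reg, tgt in self.positives:
            if reg == tgt:
                raise UniverseMismatchError(f"self-loop {reg}->{tgt} in gold standard")
            if reg not in self.universe or tgt not in self.universe:
                raise UniverseMismatchError(
                    f"gold edge {reg}->{tgt} outside the gene universe"
                )

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(reg for reg, _ in self.positives)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    ACC: float
    F: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict:
        d = {"SN": self.SN, "SP": self.SP, "ACC": self.ACC,
             "F": self.F, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def collapse_undirected(gold: GoldStandard) -> dict[Pair, bool]:
    """Label every unordered pair of distinct genes.

    A pair is positive iff either direction appears among the gold
    positives; all remaining pairs are negative.
    """
    if not gold.universe:
        raise UniverseMismatchError("empty gene universe")
    pos = {_canon(r, t) for r, t in gold.positives}
    return {
        _canon(a, b): (_canon(a, b) in pos)
        for a, b in combinations(sorted(gold.universe), 2)
    }


def confusion_at_selection(
    selected: EdgeList, labels: dict[Pair, bool]
) -> ConfusionCounts:
    """Confusion counts of a selected edge set against pair labels."""
    chosen: set[Pair] = set()
    for e in selected.edges:
        pair = _canon(e.gene_a, e.gene_b)
        if pair not in labels:
            raise UniverseMismatchError(
                f"selected pair {pair[0]}--{pair[1]} outside the gold universe"
            )
        chosen.add(pair)
    tp = sum(1 for p in chosen if labels[p])
    fp = len(chosen) - tp
    n_pos = sum(1 for v in labels.values() if v)
    fn = n_pos - tp
    tn = len(labels) - n_pos - fp
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _safe_div(num: float, den: float, default: float = 0.0) -> float:
    return num / den if den != 0 else default


def point_metrics(c: ConfusionCounts) -> MetricSet:
    """SN, SP, ACC, F-measure and MCC at one operating point.

    MCC is defined as 0 when any factor of its denominator is zero (the
    common benchmark convention for empty prediction classes); such cases
    are logged.
    """
    sn = _safe_div(c.TP, c.TP + c.FN)
    sp = _safe_div(c.TN, c.TN + c.FP)
    acc = _safe_div(c.TP + c.TN, c.total)
    f = _safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    den = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if den == 0:
        logger.info("MCC denominator zero (counts %s); using 0 by convention", c)
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(den)
    return MetricSet(SN=sn, SP=sp, ACC=acc, F=f, MCC=mcc)


def roc_auc(
    edges: EdgeList, labels: dict[Pair, bool]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC of a ranked edge list.

    The ranked list induces one operating point per distinct score; pairs
    absent from the list form a final tie group.  Ties contribute diagonal
    segments, so the result equals the tie-corrected normalised
    Mann-Whitney count of (positive, negative) score pairs.
    """
    n_pos = sum(1 for v in labels.values() if v)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: labels contain a single class")

    score_of: dict[Pair, float] = {}
    for e in edges.edges:
        pair = _canon(e.gene_a, e.gene_b)
        if pair not in labels:
            raise UniverseMismatchError(
                f"ranked pair {pair[0]}--{pair[1]} outside the gold universe"
            )
        # the effective ranking key: |score| when the list was ranked that way
        score_of[pair] = abs(e.score) if edges.ranked_by_absolute else e.score

    # group pairs by ranking key; unranked pairs form one sentinel group last
    groups: dict[float, list[bool]] = {}
    sentinel: list[bool] = []
    for pair, is_pos in labels.items():
        if pair in score_of:
            groups.setdefault(score_of[pair], []).append(is_pos)
        else:
            sentinel.append(is_pos)
    ordered = [groups[k] for k in sorted(groups, reverse=True)]
    if sentinel:
        ordered.append(sentinel)

    points = [(0.0, 0.0)]
    tp = fp = 0
    auc = 0.0
    for grp in ordered:
        dp = sum(grp)
        dn = len(grp) - dp
        # trapezoid over the tie group's diagonal segment
        auc += dn / n_neg * (tp + dp / 2.0) / n_pos
        tp += dp
        fp += dn
        points.append((fp / n_neg, tp / n_pos))
    return points, auc
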