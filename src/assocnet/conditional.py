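"""Conditional association measures.

Pairwise coexpression cannot tell a direct regulation X -> Y from an
indirect chain X -> Z -> Y or a common regulator Z -> (X, Y).  Conditioning
on a third gene Z prunes such false positives: partial correlation and
conditional mutual information vanish (in population) when X and Y are
independent given Z, while liquid association asks the opposite question --
whether the X-Y coexpression itself changes with the level of Z.

Conditioning is restricted to a single gene Z.  The measures are registered
in :data:`CONDITIONAL_REGISTRY` under the names PartialPearson, CMI and LA.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.stats import norm, rankdata

from .errors import CollinearityError, DegenerateInputError, ParameterError
from .measures import (
    MeasureValue,
    _as_pair,
    _equal_frequency_bins,
    _require_variation,
    _resolve_bins,
    pearson,
)

__all__ = [
    "partial_correlation",
    "conditional_mi",
    "liquid_association",
    "strongest_common_neighbor",
    "conditional_association",
    "CONDITIONAL_REGISTRY",
    "compute_conditional",
]


def _as_triple(x, y, z, min_n: int = 2):
    x, y = _as_pair(x, y, min_n=min_n)
    z = np.asarray(z, dtype=float).ravel()
    if z.shape != x.shape:
        raise ParameterError(
            f"conditioning vector length {z.size} != sample count {x.size}"
        )
    if not np.isfinite(z).all():
        raise DegenerateInputError("non-finite values in conditioning vector")
    return x, y, z


def partial_correlation(x, y, z) -> MeasureValue:
    """First-order partial Pearson correlation r_XY.Z in [-1, 1].

    r_XY.Z = (r_XY - r_XZ r_YZ) / sqrt((1 - r_XZ^2)(1 - r_YZ^2)).

    Equals the Pearson correlation of the residuals of X and Y after linear
    regression on Z.  Raises :class:`CollinearityError` when either argument
    is (numerically) collinear with Z, where the denominator vanishes.
    """
    x, y, z = _as_triple(x, y, z)
    _require_variation(x, y, z)
    r_xy = pearson(x, y).value
    r_xz = pearson(x, z).value
    r_yz = pearson(y, z).value
    den2 = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if den2 <= 1e-24:
        raise CollinearityError("argument collinear with conditioning gene")
    value = (r_xy - r_xz * r_yz) / math.sqrt(den2)
    return MeasureValue(
        float(np.clip(value, -1.0, 1.0)), "PartialPearson", (-1.0, 1.0)
    )


def conditional_mi(x, y, z, bins=None) -> MeasureValue:
    """Plug-in conditional mutual information I(X; Y | Z) >= 0 (nats).

    All three variables are discretised by the same equal-frequency rule as
    :func:`~assocnet.measures.mutual_information` (default ceil(n^(1/3))
    bins) and

        I(X;Y|Z) = sum p(x,y,z) log[ p(x,y,z) p(z) / (p(x,z) p(y,z)) ]

    is evaluated on the three-way contingency table.  A constant Z collapses
    to a single bin, so the statistic then reduces exactly to I(X; Y).

    With the default sqrt-rule the three-way table is very sparse for large
    n; pass an explicit small ``bins`` for conditioning analyses.
    """
    x, y, z = _as_triple(x, y, z)
    _require_variation(x, y)
    n = x.size
    nbins = _resolve_bins(bins, n)
    bx = _equal_frequency_bins(x, nbins)
    by = _equal_frequency_bins(y, nbins)
    bz = _equal_frequency_bins(z, nbins)
    joint = np.zeros((bx.max() + 1, by.max() + 1, bz.max() + 1))
    np.add.at(joint, (bx, by, bz), 1.0)
    joint /= n
    p_z = joint.sum(axis=(0, 1), keepdims=True)
    p_xz = joint.sum(axis=1, keepdims=True)
    p_yz = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = (joint * p_z)[mask] / (p_xz * p_yz)[mask]
    value = float(np.sum(joint[mask] * np.log(ratio)))
    return MeasureValue(max(0.0, value), "CMI", (0.0, math.inf), {"bins": nbins})


def liquid_association(x, y, z, transform: bool = True) -> MeasureValue:
    """Liquid association LA(X,Y | Z) = mean(X_i Y_i Z_i).

    Measures how the X-Y coexpression co-varies with the level of a third
    gene Z; it is odd in Z (negating Z flips the sign) and near zero when Z
    is unrelated to the X-Y relationship.

    With ``transform=True`` (default) x and y are z-scored and z is mapped
    to normal scores (Blom quantiles of its ranks) before averaging, since
    the raw triple-product average is scale-dependent and not comparable
    across genes.  ``transform=False`` evaluates the raw average for inputs
    that are already standardised.
    """
    x, y, z = _as_triple(x, y, z)
    _require_variation(x, y)
    if transform:
        _require_variation(z)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        r = rankdata(z, method="average")
        z = norm.ppf((r - 0.375) / (z.size + 0.25))
    value = float(np.mean(x * y * z))
    return MeasureValue(value, "LA", (-math.inf, math.inf), {"transform": transform})


def strongest_common_neighbor(assoc, i: int, j: int) -> int | None:
    """Index of the conditioning gene for pair (i, j): the gene whose weaker
    link to the pair is strongest, argmax_k min(|s_ik|, |s_jk|).

    This is a pruning heuristic, not part of the conditional measures'
    definitions: a gene strongly associated with both members of a pair is
    the natural single-gene explanation to test for an indirect path.
    Returns None when no third gene has finite scores to both members.
    """
    scores = np.abs(np.asarray(assoc.scores, dtype=float))
    m = scores.shape[0]
    best, best_val = None, -np.inf
    for k in range(m):
        if k in (i, j):
            continue
        s_ik, s_jk = scores[i, k], scores[j, k]
        if np.isnan(s_ik) or np.isnan(s_jk):
            continue
        val = min(s_ik, s_jk)
        if val > best_val:
            best, best_val = k, val
    return best


def conditional_association(
    expr, assoc, name: str = "PartialPearson", **kwargs
) -> np.ndarray:
    """Conditional score for every gene pair, conditioning each pair on its
    strongest common neighbor in `assoc` (NaN where no neighbor exists or
    the measure degenerates).

    `expr` is an ExpressionMatrix and `assoc` a matching AssociationMatrix;
    the returned m x m array prunes indirect regulations: a pair whose
    association collapses under conditioning is likely linked through the
    conditioning gene rather than directly.
    """
    from .errors import AssocnetError

    if tuple(expr.gene_ids) != tuple(assoc.gene_ids):
        raise AssocnetError("expression and association gene ids disagree")
    m = expr.n_genes
    out = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            k = strongest_common_neighbor(assoc, i, j)
            if k is None:
                continue
            try:
                mv = compute_conditional(
                    name, expr.values[i], expr.values[j], expr.values[k],
                    **kwargs,
                )
            except (DegenerateInputError, CollinearityError):
                continue
            out[i, j] = out[j, i] = mv.value
    return out


CONDITIONAL_REGISTRY: dict[str, Callable[..., MeasureValue]] = {
    "PartialPearson": partial_correlation,
    "CMI": conditional_mi,
    "LA": liquid_association,
}


def compute_conditional(name: str, x, y, conditioning, **kwargs) -> MeasureValue:
    """Evaluate a registered conditional measure by name."""
    try:
        func = CONDITIONAL_REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown conditional measure {name!r}; "
            f"known: {', '.join(CONDITIONAL_REGISTRY)}"
        ) from None
    return func(x, y, conditioning, **kwargs)
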