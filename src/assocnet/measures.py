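"""Pairwise association measures for gene expression vectors.

Fourteen estimators of the dependence between two genes' expression profiles
X = (X1,...,Xn) and Y = (Y1,...,Yn), spanning linear correlation (Pearson,
Wilks), rank correlation (Spearman, Kendall, Hoeffding, Blomqvist,
Goodman-Kruskal, WWH), information-theoretic dependence (MI, MIC) and
kernel / copula dependence (KCCA, dCor, cMMD, RDC).  Each returns a
:class:`MeasureValue` carrying the score, its declared range and the
parameters used.  All measures are exchange-symmetric: M(x, y) == M(y, x).

A string-keyed registry (:data:`REGISTRY`, :func:`compute`) lets pipelines
select measures by their conventional abbreviation.

Conventions
-----------
* Ranks use average ranks for ties unless a measure's definition requires
  otherwise (Hoeffding's bivariate rank counts strict inequalities).
* The empirical copula transform is u_i = rank(x_i) / n with average ranks,
  so values lie in (0, 1].
* Degenerate inputs (constant vectors, all-tied ranks) raise
  :class:`~assocnet.errors.DegenerateInputError` rather than returning NaN.
* Hoeffding's D is implemented exactly as the classical rational expression
  (without the conventional factor 30); its empirical range is [-1/60, 1/30]
  asymptotically, not the nominal [0, 1] -- range checks treat it as exempt.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .errors import (
    CombinatorialExplosionError,
    DegenerateInputError,
    ParameterError,
    SampleSizeError,
)

__all__ = [
    "MeasureValue",
    "MeasureInfo",
    "REGISTRY",
    "compute",
    "measure_names",
    "pearson",
    "spearman",
    "kendall_tau",
    "hoeffding_d",
    "blomqvist_beta",
    "goodman_kruskal_gamma",
    "wwh",
    "mutual_information",
    "mic",
    "wilks_w",
    "kcca",
    "dcor",
    "cmmd",
    "rdc",
]

UNBOUNDED = math.inf


@dataclass(frozen=True)
class MeasureValue:
    """One measure's score for one gene pair."""

    value: float
    measure_id: str
    range: tuple[float, float]
    params: dict = field(default_factory=dict)
    seed: int | None = None


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _as_pair(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_n:
        raise SampleSizeError(f"need at least {min_n} samples, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("non-finite values in input")
    return x, y


def _require_variation(*vecs: np.ndarray) -> None:
    for v in vecs:
        if np.ptp(v) == 0.0:
            raise DegenerateInputError("constant input vector")


def _copula(v: np.ndarray) -> np.ndarray:
    """Empirical CDF transform rank/n with average ranks; values in (0, 1]."""
    return rankdata(v, method="average") / v.size


def _median_heuristic(v: np.ndarray) -> float:
    d = np.abs(v[:, None] - v[None, :])
    d = d[np.triu_indices(v.size, k=1)]
    d = d[d > 0]
    if d.size == 0:
        raise DegenerateInputError("all pairwise distances zero")
    return float(np.median(d))


def _gaussian_gram(v: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = (v[:, None] - v[None, :]) ** 2
    return np.exp(-d2 / (2.0 * bandwidth**2))


def _center_gram(k: np.ndarray) -> np.ndarray:
    n = k.shape[0]
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    return h @ k @ h


def _concordance_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Concordant / discordant pair counts; ties count as neither."""
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(x.size, k=1)
    upper = prod[iu]
    return int(np.count_nonzero(upper > 0)), int(np.count_nonzero(upper < 0))


# ---------------------------------------------------------------------------
# product-moment and rank correlations
# ---------------------------------------------------------------------------


def pearson(x, y) -> MeasureValue:
    """Pearson product-moment correlation r in [-1, 1].

    r = sum((Xi - Xbar)(Yi - Ybar)) / ((n-1) SX SY) with the sample (n-1)
    standard deviations; the (n-1) factors cancel against np.corrcoef's
    normalisation, so the two agree exactly.
    """
    x, y = _as_pair(x, y)
    _require_variation(x, y)
    xd = x - x.mean()
    yd = y - y.mean()
    r = float(xd @ yd / np.sqrt((xd @ xd) * (yd @ yd)))
    return MeasureValue(float(np.clip(r, -1.0, 1.0)), "Pearson", (-1.0, 1.0))


def spearman(x, y) -> MeasureValue:
    """Spearman rank correlation rho in [-1, 1].

    Without ties this equals 1 - 6*sum(d_i^2)/(n(n^2-1)) with d_i the rank
    differences; with ties it is Pearson correlation of the average-rank
    vectors (the two definitions coincide in the tie-free case).
    """
    x, y = _as_pair(x, y)
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        raise DegenerateInputError("all-tied input for rank correlation")
    r = pearson(rx, ry).value
    return MeasureValue(r, "Spearman", (-1.0, 1.0))


def kendall_tau(x, y) -> MeasureValue:
    """Kendall tau (tau-a): (n_c - n_d) / (n(n-1)/2).

    Tied pairs are neither concordant nor discordant; the denominator stays
    the total pair count n(n-1)/2.
    """
    x, y = _as_pair(x, y)
    _require_variation(x, y)
    nc, nd = _concordance_counts(x, y)
    n = x.size
    value = (nc - nd) / (n * (n - 1) / 2)
    return MeasureValue(float(value), "Kendall", (-1.0, 1.0))


def hoeffding_d(x, y) -> MeasureValue:
    """Hoeffding's dependence statistic D.

    D = [(n-2)(n-3) D1 + D2 - 2(n-2) D3] / [n(n-1)(n-2)(n-3)(n-4)] with
    D1 = sum (Q_i-1)(Q_i-2), D2 = sum (R_i-1)(R_i-2)(S_i-1)(S_i-2),
    D3 = sum (R_i-2)(S_i-2)(Q_i-1); R, S are (average) univariate ranks and
    Q_i = #{j : X_j < X_i and Y_j < Y_i} is the strict bivariate rank.
    Requires n >= 5.  See the module docstring for the range caveat.
    """
    x, y = _as_pair(x, y, min_n=5)
    _require_variation(x, y)
    n = x.size
    r = rankdata(x, method="average")
    s = rankdata(y, method="average")
    q = np.count_nonzero(
        (x[None, :] < x[:, None]) & (y[None, :] < y[:, None]), axis=1
    ).astype(float)
    d1 = float(np.sum((q - 1) * (q - 2)))
    d2 = float(np.sum((r - 1) * (r - 2) * (s - 1) * (s - 2)))
    d3 = float(np.sum((r - 2) * (s - 2) * (q - 1)))
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    den = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return MeasureValue(num / den, "Hoeffding", (0.0, 1.0))


def blomqvist_beta(x, y) -> MeasureValue:
    """Blomqvist's medial correlation beta = (n1 - n2) / (n1 + n2).

    The plane is split into quadrants by the two sample medians; n1 counts
    points in quadrants I/III, n2 in II/IV.  Points falling exactly on a
    median line are dropped before counting (the standard convention for odd
    sample sizes and ties).
    """
    x, y = _as_pair(x, y)
    _require_variation(x, y)
    mx, my = np.median(x), np.median(y)
    off = (x != mx) & (y != my)
    xs, ys = x[off], y[off]
    n1 = int(np.count_nonzero(((xs > mx) & (ys > my)) | ((xs < mx) & (ys < my))))
    n2 = int(off.sum()) - n1
    if n1 + n2 == 0:
        raise DegenerateInputError("all points on a median line")
    return MeasureValue((n1 - n2) / (n1 + n2), "Blomqvist", (-1.0, 1.0))


def goodman_kruskal_gamma(x, y) -> MeasureValue:
    """Goodman-Kruskal gamma G = (n_s - n_d) / (n_s + n_d).

    Like Kendall's tau but normalised by the untied pair count only, so
    tied pairs are excluded from numerator and denominator.
    """
    x, y = _as_pair(x, y)
    _require_variation(x, y)
    nc, nd = _concordance_counts(x, y)
    if nc + nd == 0:
        raise DegenerateInputError("no concordant or discordant pairs")
    return MeasureValue((nc - nd) / (nc + nd), "Goodman", (-1.0, 1.0))


def wwh(x, y, k: int = 3, consecutive: bool = False) -> MeasureValue:
    """WWH order-pattern count statistic.

    Counts length-k index subsequences on which the within-subsequence rank
    patterns of x and y are identical or exactly reversed (the indicator F
    adopted here).  Counting reversed patterns as well makes the statistic
    sensitive to inhibitory as much as activating regulation, mirroring how
    the published count-statistic coexpression measures treat negative
    association.  By default the sum runs over all C(n, k) index subsets
    (the general i.i.d.-sample case), guarded against combinatorial
    explosion at 10^6 subsets; with ``consecutive=True`` it runs over the
    n-k+1 sliding windows only (the time-series special case).
    """
    x, y = _as_pair(x, y)
    n = x.size
    if not 2 <= k <= n:
        raise ParameterError(f"k must be in [2, n]; got k={k}, n={n}")
    if consecutive:
        xw = sliding_window_view(x, k)
        yw = sliding_window_view(y, k)
    else:
        n_subsets = math.comb(n, k)
        if n_subsets > 1_000_000:
            raise CombinatorialExplosionError(
                f"C({n},{k}) = {n_subsets} subsets exceeds the 1e6 guard; "
                "use consecutive=True"
            )
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), k)),
            dtype=np.intp,
        ).reshape(-1, k)
        xw = x[idx]
        yw = y[idx]
    rx = rankdata(xw, method="average", axis=1)
    ry = rankdata(yw, method="average", axis=1)
    same = np.all(rx == ry, axis=1)
    reversed_ = np.all(rx == (k + 1) - ry, axis=1)
    count = int(np.count_nonzero(same | reversed_))
    return MeasureValue(
        float(count), "WWH", (0.0, UNBOUNDED), {"k": k, "consecutive": consecutive}
    )


# ---------------------------------------------------------------------------
# information-theoretic measures
# ---------------------------------------------------------------------------


def _equal_frequency_bins(v: np.ndarray, bins: int) -> np.ndarray:
    """Quantile-edge discretisation into at most `bins` classes.

    Edges are the interior quantiles of v; duplicate edges (heavy ties)
    collapse, so a constant vector maps to a single class.
    """
    edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, v, side="left")


def _resolve_bins(bins, n: int) -> int:
    if bins is None or bins == "cbrt":
        # cube-root rule: keeps the plug-in bias ~(b-1)^2/(2n) small enough
        # that independent inputs score near zero even at large n
        bins = int(math.ceil(n ** (1.0 / 3.0)))
    elif bins == "sqrt":
        bins = int(math.ceil(math.sqrt(n)))
    bins = int(bins)
    if bins < 2:
        raise ParameterError(f"need at least 2 bins, got {bins}")
    return bins


def _plugin_mi(bx: np.ndarray, by: np.ndarray, base: float) -> float:
    """Plug-in mutual information of two discrete label vectors."""
    n = bx.size
    joint = np.zeros((bx.max() + 1, by.max() + 1))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (px @ py)[mask]
    return float(np.sum(joint[mask] * np.log(ratio)) / math.log(base))


def mutual_information(x, y, bins=None, base: float = math.e) -> MeasureValue:
    """Plug-in mutual information I(X; Y) >= 0.

    Continuous inputs are discretised by equal-frequency binning (default
    ceil(n^(1/3)) bins; "sqrt" or an integer select other rules) and
    I = sum P(x,y) log[P(x,y) / (P(x)P(y))] is evaluated on the contingency
    table.  Units are nats by default (``base=2`` for bits).
    """
    x, y = _as_pair(x, y)
    _require_variation(x, y)
    nbins = _resolve_bins(bins, x.size)
    bx = _equal_frequency_bins(x, nbins)
    by = _equal_frequency_bins(y, nbins)
    value = max(0.0, _plugin_mi(bx, by, base))
    return MeasureValue(value, "MI", (0.0, UNBOUNDED), {"bins": nbins, "base": base})


def mic(x, y, budget: float | None = None) -> MeasureValue:
    """Maximal information coefficient over equal-frequency grids.

    MIC = max over grid shapes (p, q) with p*q < B of
    I_bits(X, Y on the p-by-q grid) / log2(min(p, q)), with the default
    budget B = n^0.6.  Axis partitions are equal-frequency; the exhaustive
    boundary optimisation of the original MINE algorithm is not performed,
    so this is a deterministic lower bound of the full MIC.
    """
    x, y = _as_pair(x, y, min_n=4)
    _require_variation(x, y)
    n = x.size
    b = float(n**0.6) if budget is None else float(budget)
    shapes = [
        (p, q)
        for p in range(2, int(b) + 1)
        for q in range(2, int(b) + 1)
        if p * q < b
    ]
    if not shapes:
        raise ParameterError(f"grid budget B={b:.3g} admits no p,q >= 2 grid")
    best = 0.0
    col_cache: dict[int, np.ndarray] = {}
    row_cache: dict[int, np.ndarray] = {}
    for p, q in shapes:
        if p not in row_cache:
            row_cache[p] = _equal_frequency_bins(x, p)
        if q not in col_cache:
            col_cache[q] = _equal_frequency_bins(y, q)
        i_bits = _plugin_mi(row_cache[p], col_cache[q], 2.0)
        best = max(best, i_bits / math.log2(min(p, q)))
    return MeasureValue(min(best, 1.0), "MIC", (0.0, 1.0), {"B": b})


# ---------------------------------------------------------------------------
# covariance / kernel / copula measures
# ---------------------------------------------------------------------------


def wilks_w(x, y) -> MeasureValue:
    """Wilks' statistic W = 1 - det(Sigma) / (det(Sigma11) det(Sigma22)).

    For two univariate vectors the joint covariance matrix is 2x2 and W
    reduces algebraically to the squared Pearson correlation r^2.
    """
    x, y = _as_pair(x, y)
    _require_variation(x, y)
    sigma = np.cov(np.vstack([x, y]))
    det = float(np.linalg.det(sigma))
    w = 1.0 - det / (sigma[0, 0] * sigma[1, 1])
    return MeasureValue(float(np.clip(w, 0.0, 1.0)), "Wilks", (0.0, 1.0))


def kcca(x, y, bandwidth: float | None = None, reg: float = 0.1) -> MeasureValue:
    """Regularised kernel canonical correlation in [0, 1].

    Gaussian-kernel Gram matrices of each variable (median-heuristic
    bandwidth by default) are centred, and the first kernel canonical
    correlation is computed as the largest singular value of

        (K_x + reg I)^{-1} K_x  .  K_y (K_y + reg I)^{-1},

    the generalised-eigenproblem form of kernel CCA with a ridge term on
    each Gram factor.  Without regularisation the empirical problem is
    degenerate (the score saturates at 1 for any data), hence reg > 0 is
    required.  Deterministic given inputs and parameters.
    """
    x, y = _as_pair(x, y, min_n=4)
    _require_variation(x, y)
    if reg <= 0:
        raise ParameterError("reg must be positive; unregularised KCCA is degenerate")
    bx = _median_heuristic(x) if bandwidth is None else float(bandwidth)
    by = _median_heuristic(y) if bandwidth is None else float(bandwidth)
    if bx <= 0 or by <= 0:
        raise ParameterError("bandwidth must be positive")
    n = x.size
    kx = _center_gram(_gaussian_gram(x, bx))
    ky = _center_gram(_gaussian_gram(y, by))
    eye = np.eye(n)
    a = np.linalg.solve(kx + reg * eye, kx)
    b = ky @ np.linalg.inv(ky + reg * eye)
    rho = float(np.linalg.svd(a @ b, compute_uv=False)[0])
    return MeasureValue(
        float(np.clip(rho, 0.0, 1.0)), "KCCA", (0.0, 1.0), {"reg": reg}
    )


def dcor(x, y) -> MeasureValue:
    """Distance correlation in [0, 1]; zero iff empirical distance covariance
    vanishes (population dCor = 0 characterises independence).

    Pairwise Euclidean distance matrices are double-centred (row, column and
    grand means removed); V2_xy = mean(A * B) is the squared distance
    covariance and dCor = sqrt(V2_xy / (V_x V_y)), with 0 returned when
    either marginal distance variance is zero.
    """
    x, y = _as_pair(x, y)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])

    def _dc(m):
        return m - m.mean(axis=0, keepdims=True) - m.mean(axis=1, keepdims=True) + m.mean()

    aa, bb = _dc(a), _dc(b)
    v2xy = float(np.mean(aa * bb))
    v2x = float(np.mean(aa * aa))
    v2y = float(np.mean(bb * bb))
    if v2x <= 0.0 or v2y <= 0.0:
        return MeasureValue(0.0, "dCor", (0.0, 1.0))
    r2 = v2xy / math.sqrt(v2x * v2y)
    return MeasureValue(float(np.clip(math.sqrt(max(r2, 0.0)), 0.0, 1.0)),
                        "dCor", (0.0, 1.0))


def cmmd(
    x,
    y,
    bandwidth: float | None = None,
    variant: str = "independence_contrast",
) -> MeasureValue:
    """Copula-based maximum mean discrepancy, clipped to [0, 1].

    Both arguments are mapped through their empirical CDFs to copula values
    u, v in (0, 1], and a Gaussian kernel MMD statistic is evaluated:

    * ``independence_contrast`` (default): the MMD between the paired copula
      sample {(u_i, v_i)} and the product of its marginals, under the
      product Gaussian kernel.  This has the closed form
      sqrt(tr(H K_u H K_v)) / n with H the centring matrix, is zero in
      population exactly under independence, deterministic, and exactly
      exchange-symmetric.
    * ``as_printed``: the literal two-marginal U-statistic
      (1/(n(n-1))) sum_{i != j} [phi(u_i,u_j) + phi(v_i,v_j)
      - phi(u_i,v_j) - phi(u_j,v_i)], i.e. the unbiased squared MMD between
      the two (near-uniform) copula marginals; kept for auditability -- it
      is close to zero for any dependence structure.
    """
    x, y = _as_pair(x, y, min_n=4)
    _require_variation(x, y)
    u = _copula(x)
    v = _copula(y)
    if bandwidth is None:
        bandwidth = _median_heuristic(np.concatenate([u, v]))
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    params = {"bandwidth": bandwidth, "variant": variant}
    if variant == "independence_contrast":
        ku = _gaussian_gram(u, bandwidth)
        kv = _gaussian_gram(v, bandwidth)
        n = u.size
        h = np.eye(n) - np.full((n, n), 1.0 / n)
        mmd2 = float(np.trace(h @ ku @ h @ kv)) / n**2
        value = math.sqrt(max(mmd2, 0.0))
    elif variant == "as_printed":
        phi_uu = _gaussian_gram(u, bandwidth)
        phi_vv = _gaussian_gram(v, bandwidth)
        phi_uv = np.exp(-((u[:, None] - v[None, :]) ** 2) / (2 * bandwidth**2))
        n = u.size
        off = ~np.eye(n, dtype=bool)
        total = float(
            phi_uu[off].sum() + phi_vv[off].sum() - 2.0 * phi_uv[off].sum()
        )
        value = total / (n * (n - 1))
    else:
        raise ParameterError(f"unknown cmmd variant {variant!r}")
    return MeasureValue(float(np.clip(value, 0.0, 1.0)), "CMMD", (0.0, 1.0), params)


def _first_canonical_correlation(fa: np.ndarray, fb: np.ndarray) -> float:
    """Largest canonical correlation between two column-centred feature sets."""
    fa = fa - fa.mean(axis=0)
    fb = fb - fb.mean(axis=0)

    def _orth(m):
        u, s, _ = np.linalg.svd(m, full_matrices=False)
        keep = s > s[0] * 1e-9 if s.size and s[0] > 0 else slice(0)
        return u[:, keep]

    qa, qb = _orth(fa), _orth(fb)
    if qa.shape[1] == 0 or qb.shape[1] == 0:
        raise DegenerateInputError("rank-zero feature matrix in CCA")
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(s[0])


def rdc(x, y, k: int = 20, s: float = 0.6, seed: int = 0) -> MeasureValue:
    """Randomized dependence coefficient in [0, 1].

    Copula-transform each argument, append an intercept, project through k
    random normal weights scaled by s, take sinusoidal features, and return
    the largest canonical correlation between the two feature sets.  The
    defaults k=20, s=0.6 follow the convention adopted here.  One weight
    matrix drawn from `seed` is shared by both arguments, which makes the
    coefficient exactly symmetric under argument exchange and invariant
    under strictly increasing transforms of either argument (the copula
    values are unchanged).  Identical (inputs, k, s, seed) give identical
    values.
    """
    x, y = _as_pair(x, y, min_n=5)
    _require_variation(x, y)
    if x.size <= k:
        raise ParameterError(f"need n > k; got n={x.size}, k={k}")
    if s <= 0:
        raise ParameterError("scale s must be positive")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((2, k))
    au = np.column_stack([_copula(x), np.ones(x.size)])
    av = np.column_stack([_copula(y), np.ones(y.size)])
    fu = np.sin((s / 2.0) * (au @ w))
    fv = np.sin((s / 2.0) * (av @ w))
    rho = _first_canonical_correlation(fu, fv)
    return MeasureValue(
        float(np.clip(rho, 0.0, 1.0)), "RDC", (0.0, 1.0), {"k": k, "s": s}, seed
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasureInfo:
    """Registry entry: how a pipeline should call and rank a measure."""

    name: str
    func: Callable[..., MeasureValue]
    range: tuple[float, float]
    signed: bool  # ranges below zero: rank by |score| by default
    stochastic: bool  # accepts a seed
    range_exempt: bool = False  # empirical values may leave the nominal range


REGISTRY: dict[str, MeasureInfo] = {
    m.name: m
    for m in [
        MeasureInfo("Pearson", pearson, (-1, 1), True, False),
        MeasureInfo("Spearman", spearman, (-1, 1), True, False),
        MeasureInfo("Kendall", kendall_tau, (-1, 1), True, False),
        MeasureInfo("Hoeffding", hoeffding_d, (0, 1), False, False, True),
        MeasureInfo("Blomqvist", blomqvist_beta, (-1, 1), True, False),
        MeasureInfo("Goodman", goodman_kruskal_gamma, (-1, 1), True, False),
        MeasureInfo("WWH", wwh, (0, UNBOUNDED), False, False),
        MeasureInfo("MI", mutual_information, (0, UNBOUNDED), False, False),
        MeasureInfo("MIC", mic, (0, 1), False, False),
        MeasureInfo("Wilks", wilks_w, (0, 1), False, False),
        MeasureInfo("KCCA", kcca, (0, 1), False, False),
        MeasureInfo("dCor", dcor, (0, 1), False, False),
        MeasureInfo("CMMD", cmmd, (0, 1), False, False),
        MeasureInfo("RDC", rdc, (0, 1), False, True),
    ]
}


def measure_names() -> list[str]:
    """Registered measure abbreviations, in canonical (Table) order."""
    return list(REGISTRY)


def compute(
    name: str, x, y, params: dict | None = None, seed: int | None = None
) -> MeasureValue:
    """Evaluate a registered measure by name.

    `params` are keyword arguments for the measure; `seed` is forwarded to
    stochastic measures only.
    """
    try:
        info = REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown measure {name!r}; known: {', '.join(REGISTRY)}"
        ) from None
    kwargs = dict(params or {})
    if info.stochastic and seed is not None:
        kwargs.setdefault("seed", seed)
    return info.func(x, y, **kwargs)
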