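"""Spatial statistics: Moran's I, correlograms, the modified t-test of
spatial association, distance-based autocovariates, and permutation tests
on model residuals.

All distances are Euclidean in the projected (equal-area) plane, consistent
with the grid construction.  The modified t-test corrects the degrees of
freedom of a Pearson correlation between two spatial fields for the
autocorrelation of both fields (Dutilleul's effective-sample-size
correction): naive tests on autocorrelated maps reject far too often
because nearby cells are not independent observations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree, distance_matrix


@dataclasses.dataclass
class SpatialField:
    """Values indexed by projected cell centroids.

    The common currency of every spatial statistic in the pipeline: cell
    ids, centroid coordinates in metres, and one value per cell.
    """

    ids: np.ndarray  # (n,) object/str
    coords: np.ndarray  # (n, 2) projected metres
    values: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n, 2)")
        if self.values.shape != (n,):
            raise ValueError("values must be (n,)")
        if len(set(map(str, self.ids))) != n:
            raise ValueError("duplicated cell ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.ids)

    def with_values(self, values) -> "SpatialField":
        return SpatialField(self.ids, self.coords, np.asarray(values, dtype=float))


@dataclasses.dataclass(frozen=True)
class ModifiedTTestResult:
    r: float
    ess: float  # effective sample size
    f_stat: float
    p: float
    n: int


@dataclasses.dataclass(frozen=True)
class MoranResult:
    i: float
    expected: float  # -1 / (n - 1)
    p_perm: float
    n_perm: int


class ConstantFieldError(ValueError):
    """A statistic is undefined because the field has zero variance."""


def moran_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an arbitrary non-negative weight matrix.

    ``I = (n / sum W) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with centred
    values ``z``.  The diagonal of ``weights`` must be zero.
    """
    z = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 cells")
    if w.shape != (n, n):
        raise ValueError("weights shape mismatch")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix must have zero diagonal")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("weight matrix is all zero")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ConstantFieldError("zero-variance field")
    return float(n / s0 * (z @ w @ z) / denom)


def distance_classes(coords: np.ndarray, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width distance classes over the observed pairwise distances.

    Returns (dist_matrix, class_matrix) where class_matrix[i, j] in
    ``0 .. n_classes-1`` (diagonal entries are -1).
    """
    d = distance_matrix(coords, coords)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all points coincide")
    width = dmax / n_classes
    cls = np.minimum((d / width).astype(int), n_classes - 1)
    np.fill_diagonal(cls, -1)
    return d, cls


def _perm_pvalue(observed: float, permuted: np.ndarray, alternative: str) -> float:
    n_perm = permuted.size
    if alternative == "greater":
        extreme = np.sum(permuted >= observed)
    elif alternative == "less":
        extreme = np.sum(permuted <= observed)
    elif alternative == "two-sided":
        lo = (1 + np.sum(permuted <= observed)) / (1 + n_perm)
        hi = (1 + np.sum(permuted >= observed)) / (1 + n_perm)
        return float(min(1.0, 2 * min(lo, hi)))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float((1 + extreme) / (1 + n_perm))


def correlogram(
    field: SpatialField,
    n_classes: int = 10,
    n_perm: int = 199,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> list[dict]:
    """Moran correlogram: I per equal-width distance class with permutation p.

    Classes with no pairs are reported with NaN statistics.
    """
    rng = np.random.default_rng(seed)
    _, cls = distance_classes(field.coords, n_classes)
    out = []
    values = field.values
    for h in range(n_classes):
        w = (cls == h).astype(float)
        if w.sum() == 0:
            out.append({"cls": h, "i": np.nan, "p": np.nan, "n_pairs": 0})
            continue
        obs = moran_i(values, w)
        perm = np.empty(n_perm)
        for b in range(n_perm):
            perm[b] = moran_i(rng.permutation(values), w)
        out.append(
            {"cls": h, "i": obs, "p": _perm_pvalue(obs, perm, alternative),
             "n_pairs": int(w.sum() / 2)}
        )
    return out


def _class_autocorr(z: np.ndarray, cls: np.ndarray, n_classes: int) -> np.ndarray:
    """Moment estimate of spatial autocorrelation per distance class.

    ``rho(h) = mean_{pairs in h}(z_i z_j) / mean(z^2)`` with centred z.
    Empty classes get 0 (no information).
    """
    z = z - z.mean()
    var = float(np.mean(z * z))
    cross = np.outer(z, z)
    rho = np.zeros(n_classes)
    for h in range(n_classes):
        mask = cls == h
        cnt = mask.sum()
        if cnt and var > 0:
            rho[h] = float(cross[mask].mean() / var)
    return np.clip(rho, -1.0, 1.0)


def modified_ttest(
    x: SpatialField, y: SpatialField, n_classes: int = 13
) -> ModifiedTTestResult:
    """Pearson correlation of two co-located spatial fields with
    Dutilleul's effective-sample-size correction.

    The plain Pearson r is unchanged; only the reference distribution is
    adjusted.  Spatial autocorrelation of each field is estimated per
    distance class; the implied correlation matrices Rx, Ry (entry =
    class autocorrelation of the pair's distance class, ones on the
    diagonal) are combined with the centring matrix B = I - 11'/n into

        ess = 1 + tr(B Rx) tr(B Ry) / tr(B Rx B Ry)

    (the reciprocal of the approximate variance of r under independence),
    and the test statistic F = (ess - 2) r^2 / (1 - r^2) is referred to
    F(1, ess - 2).
    """
    if len(x) != len(y) or not np.array_equal(x.ids.astype(str), y.ids.astype(str)):
        raise ValueError("fields must share the same cell set, in order")
    n = len(x)
    if n < 5:
        raise ValueError("too few cells for the modified t-test")
    xv, yv = x.values, y.values
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ConstantFieldError("correlation undefined for a constant field")
    r = float(np.corrcoef(xv, yv)[0, 1])

    _, cls = distance_classes(x.coords, n_classes)
    rho_x = _class_autocorr(xv, cls, n_classes)
    rho_y = _class_autocorr(yv, cls, n_classes)
    rx = np.where(cls >= 0, rho_x[np.maximum(cls, 0)], 1.0)
    ry = np.where(cls >= 0, rho_y[np.maximum(cls, 0)], 1.0)
    np.fill_diagonal(rx, 1.0)
    np.fill_diagonal(ry, 1.0)
    b = np.eye(n) - np.full((n, n), 1.0 / n)
    brx = b @ rx
    bry = b @ ry
    trace = float(np.trace(brx @ bry))
    if trace <= 0:
        ess = float(n)
    else:
        ess = 1.0 + float(np.trace(brx)) * float(np.trace(bry)) / trace
    ess = float(min(max(ess, 3.0), n))

    r2 = min(r * r, 1.0 - 1e-15)
    f_stat = (ess - 2.0) * r2 / (1.0 - r2)
    p = float(stats.f.sf(f_stat, 1, ess - 2.0))
    return ModifiedTTestResult(r=r, ess=ess, f_stat=f_stat, p=p, n=n)


def autocovariate(
    field: SpatialField,
    radius_m: float = 200_000.0,
    weighting: str = "inverse_distance",
) -> SpatialField:
    """Distance-weighted mean of the field over neighbours within a radius.

    ``value_i = sum_j w_ij y_j / sum_j w_ij`` over neighbours ``j`` with
    ``0 < d_ij <= radius_m``; ``weighting`` is ``"inverse_distance"`` or
    ``"equal"``.  Cells with no neighbour get NaN.  Raises if no cell has
    a neighbour at all.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if weighting not in ("inverse_distance", "equal"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    d = distance_matrix(field.coords, field.coords)
    within = (d > 0) & (d <= radius_m)
    if not within.any():
        raise ValueError("no cell has a neighbour within the radius")
    if weighting == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = np.where(within, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    else:
        w = within.astype(float)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(wsum > 0, (w @ field.values) / np.where(wsum > 0, wsum, 1.0), np.nan)
    return field.with_values(vals)


def residualize(field: SpatialField, predictors: np.ndarray) -> SpatialField:
    """OLS residuals of the field on a predictor matrix (+ intercept).

    The residual field is orthogonal to every predictor column; rank
    deficiency is an error (collinear columns must be resolved upstream).
    """
    x = np.column_stack([np.ones(len(field)), np.asarray(predictors, dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"predictor matrix is rank deficient (rank {rank} < {x.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(x, field.values, rcond=None)
    return field.with_values(field.values - x @ beta)


def knn_weights(coords: np.ndarray, k: int = 1) -> np.ndarray:
    """Symmetrized (union) k-nearest-neighbour binary adjacency.

    Distance ties are broken deterministically by point order.
    """
    n = len(coords)
    if k < 1 or k >= n:
        raise ValueError("k must be in [1, n-1]")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        for j in idx[i]:
            if j != i:
                w[i, j] = 1.0
    w = np.maximum(w, w.T)  # union symmetrization
    np.fill_diagonal(w, 0.0)
    return w


def moran_permutation_test(
    field: SpatialField,
    k_nearest: int = 1,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MoranResult:
    """Permutation Moran test on a field (typically model residuals).

    Weights are the symmetrized k-nearest-neighbour adjacency; the p-value
    uses the (1 + extreme) / (1 + n_perm) estimator, one-sided greater by
    default (positive residual clustering is the alternative of interest).
    """
    n = len(field)
    if n < 10:
        raise ValueError("need at least 10 cells")
    rng = np.random.default_rng(seed)
    w = knn_weights(field.coords, k_nearest)
    obs = moran_i(field.values, w)
    s0 = w.sum()
    z0 = field.values - field.values.mean()
    denom = float(z0 @ z0)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        z = rng.permutation(z0)
        perm[b] = n / s0 * (z @ w @ z) / denom
    return MoranResult(
        i=obs, expected=-1.0 / (n - 1),
        p_perm=_perm_pvalue(obs, perm, alternative), n_perm=n_perm,
    )
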