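"""IRT assumption diagnostics: monotonicity, local independence, dimensionality.

* Loevinger's H (Mokken scalability): observed inter-item covariances
  relative to their maximum given the item margins; item and scale
  coefficients with a bootstrap SE.  H > 0.3 supports monotone scalability.
* Yen's Q3: correlations of IRT residuals x - E[X | theta]; |Q3| > 0.2
  signals local dependence.
* Essential unidimensionality: polychoric correlations -> minimum-residual
  exploratory factor analysis -> promax rotation -> Schmid–Leiman transform
  -> ECV (>= 0.6) and omega-hierarchical (>= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .data import ItemParameterSet, ResponseMatrix, ValidationError
from .grm import expected_item_score

__all__ = [
    "MonotonicityResult",
    "LocalDependenceResult",
    "DimensionalityResult",
    "loevinger_h",
    "yen_q3",
    "polychoric_correlation",
    "polychoric_matrix",
    "bifactor_indices",
]


# ---------------------------------------------------------------------------
# Loevinger's H


@dataclass
class MonotonicityResult:
    item_pair_h: pd.DataFrame
    item_h: pd.Series
    scale_h: float
    scale_h_se: float
    cutoff: float = 0.3

    @property
    def monotone_items(self) -> set[str]:
        return set(self.item_h.index[self.item_h > self.cutoff])

    def verdict(self) -> bool:
        return bool((self.item_h > self.cutoff).all())


def _comax_matrix(S: np.ndarray) -> np.ndarray:
    """Pairwise maximum E[X_i X_j] from survival profiles.

    ``S`` has shape (m, K-1) with S[i, k] = P(X_i >= k+1).  For non-negative
    integer variables E[XY] = sum_{s,t >= 1} P(X >= s, Y >= t), and the
    comonotone (Fréchet upper bound) coupling attains min(P(X>=s), P(Y>=t)).
    """
    m, km1 = S.shape
    out = np.zeros((m, m))
    for s in range(km1):
        for t in range(km1):
            out += np.minimum(S[:, s][:, None], S[:, t][None, :])
    return out


def _scale_h_from_data(X: np.ndarray, kmax: int):
    """(pair covariances, pair max covariances) for complete-case data."""
    m = X.shape[1]
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=0)
    S = np.empty((m, kmax - 1))
    for k in range(1, kmax):
        S[:, k - 1] = (X >= k).mean(axis=0)
    comax = _comax_matrix(S)
    covmax = comax - np.outer(mean, mean)
    return cov, covmax


def loevinger_h(
    responses: ResponseMatrix,
    n_bootstrap: int = 500,
    seed: int = 0,
    cutoff: float = 0.3,
) -> MonotonicityResult:
    """Mokken scalability coefficients H_ij, H_i and scale H with bootstrap SE.

    Uses pairwise-complete data for the point estimates; the bootstrap
    resamples persons (complete cases) with a seeded generator.  Note that
    the scale H is a ratio of summed covariances, not an average of the
    item coefficients, so it need not lie between min and max item H.
    """
    df = responses.values
    items = responses.items
    m = len(items)
    kmax = max(responses.n_categories.values())
    X = df.to_numpy()

    var = np.nanvar(X, axis=0)
    dead = [items[i] for i in range(m) if not var[i] > 0]
    if dead:
        raise ValidationError(f"zero-variance item(s): {dead}")

    complete = ~np.isnan(X).any(axis=1)
    if complete.all():
        cov, covmax = _scale_h_from_data(X, kmax)
    else:  # pairwise complete
        cov = np.empty((m, m))
        covmax = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                pair = X[:, [i, j]]
                ok = ~np.isnan(pair).any(axis=1)
                c, cm = _scale_h_from_data(pair[ok], kmax)
                cov[i, j] = cov[j, i] = c[0, 1]
                covmax[i, j] = covmax[j, i] = cm[0, 1]
                cov[i, i], covmax[i, i] = c[0, 0], cm[0, 0]

    off = ~np.eye(m, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_pair = np.where(off, cov / covmax, np.nan)
    item_h = np.nansum(np.where(off, cov, 0.0), axis=1) / np.nansum(
        np.where(off, covmax, 0.0), axis=1
    )
    iu = np.triu_indices(m, 1)
    scale_h = float(cov[iu].sum() / covmax[iu].sum())

    rng = np.random.default_rng(seed)
    Xc = X[complete]
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(Xc), size=len(Xc))
        c, cm = _scale_h_from_data(Xc[idx], kmax)
        boots.append(c[iu].sum() / cm[iu].sum())
    se = float(np.std(boots, ddof=1)) if n_bootstrap > 1 else float("nan")

    return MonotonicityResult(
        item_pair_h=pd.DataFrame(h_pair, index=items, columns=items),
        item_h=pd.Series(item_h, index=items, name="H_i"),
        scale_h=scale_h,
        scale_h_se=se,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Yen's Q3


@dataclass
class LocalDependenceResult:
    q3: pd.DataFrame
    flagged_pairs: list[tuple[str, str]]
    n_pairs: int
    cutoff: float = 0.2
    signed: bool = False


def yen_q3(
    responses: ResponseMatrix,
    params: ItemParameterSet,
    thetas: pd.DataFrame | pd.Series,
    cutoff: float = 0.2,
    signed: bool = False,
    min_pair_n: int = 3,
) -> LocalDependenceResult:
    """Residual correlations Q3_ij between all item pairs.

    ``thetas`` must be scored under ``params`` (a frame with a ``theta``
    column or a plain series, indexed like the responses).  Pairs with fewer
    than ``min_pair_n`` jointly observed persons are reported as NaN.  By
    default pairs are flagged when |Q3| exceeds ``cutoff``; ``signed=True``
    compares Q3 itself.
    """
    th = thetas["theta"] if isinstance(thetas, pd.DataFrame) else thetas
    th = th.reindex(responses.persons).to_numpy()
    pm = params.for_group(None)
    items = responses.items
    m = len(items)
    resid = np.empty((len(responses), m))
    for j, it in enumerate(items):
        x = responses.values[it].to_numpy()
        resid[:, j] = x - expected_item_score(pm[it], th, params.D)

    q3 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(resid[:, i]) & ~np.isnan(resid[:, j])
            if ok.sum() < min_pair_n:
                continue
            q3[i, j] = q3[j, i] = np.corrcoef(resid[ok, i], resid[ok, j])[0, 1]

    flagged = []
    for i in range(m):
        for j in range(i + 1, m):
            v = q3[i, j]
            if np.isnan(v):
                continue
            if (abs(v) if not signed else v) > cutoff:
                flagged.append((items[i], items[j]))
    return LocalDependenceResult(
        q3=pd.DataFrame(q3, index=items, columns=items),
        flagged_pairs=flagged,
        n_pairs=m * (m - 1) // 2,
        cutoff=cutoff,
        signed=signed,
    )


# ---------------------------------------------------------------------------
# polychoric correlation (two-step ML)


def _cell_probs(rho: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for all threshold cells."""
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    pts = np.array([[a, b] for a in gx for b in gy])
    finite = np.clip(pts, -8.5, 8.5)
    C = mvn.cdf(finite).reshape(gx.size, gy.size)
    C[0, :] = 0.0
    C[:, 0] = 0.0
    P = np.diff(np.diff(C, axis=0), axis=1)
    return np.clip(P, 1e-12, None)


def polychoric_correlation(x, y) -> float:
    """Two-step ML polychoric correlation of two ordinal vectors.

    Thresholds come from the inverse-normal marginals; rho maximizes the
    contingency-table likelihood.  Empty rows/columns of the cross-table are
    handled by dropping unobserved categories; a 0.5 continuity correction
    is applied to zero cells inside the observed table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok].astype(int), y[ok].astype(int)
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    if xv.size < 2 or yv.size < 2:
        raise ValidationError("both vectors need >= 2 observed categories")
    table = np.zeros((xv.size, yv.size))
    np.add.at(table, (xi, yi), 1.0)
    if (table == 0).any():
        table = table + 0.5
    n = table.sum()
    tx = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    ty = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)

    def nll(rho):
        return -float(np.sum(table * np.log(_cell_probs(rho, tx, ty))))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(responses: ResponseMatrix) -> pd.DataFrame:
    """Pairwise-complete polychoric correlation matrix of all items."""
    items = responses.items
    m = len(items)
    R = np.eye(m)
    X = responses.values.to_numpy()
    for i in range(m):
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = polychoric_correlation(X[:, i], X[:, j])
    return pd.DataFrame(R, index=items, columns=items)


# ---------------------------------------------------------------------------
# bifactor indices via minres EFA + Schmid–Leiman


def _minres_efa(R: np.ndarray, n_factors: int, max_iter: int = 200, tol: float = 1e-7):
    """Minimum-residual factor extraction (principal-axis iterations)."""
    m = R.shape[0]
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R)) if np.linalg.det(R) > 1e-12 else np.full(m, 0.5)
    h2 = np.clip(h2, 0.05, 0.995)
    L = None
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        lv = np.clip(vals[idx], 0, None)
        L = vecs[:, idx] * np.sqrt(lv)[None, :]
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 0.995)  # Heywood clip
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    return L


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    m, k = L.shape
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / m)
        )
        T = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ T


def _promax(L: np.ndarray, power: int = 4):
    """Promax rotation: oblique target rotation of the varimax solution."""
    V = _varimax(L)
    target = np.sign(V) * np.abs(V) ** power
    Tr, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.diag(np.linalg.inv(Tr.T @ Tr))
    Tr = Tr * np.sqrt(d)[None, :]
    pattern = V @ Tr
    Tinv = np.linalg.inv(Tr)
    phi = Tinv @ Tinv.T
    return pattern, phi


@dataclass
class DimensionalityResult:
    general_loadings: pd.Series
    specific_loadings: pd.DataFrame
    ecv: float
    omega_h: float
    ecv_cutoff: float = 0.6
    omega_h_cutoff: float = 0.8

    def unidimensional(self) -> bool:
        """Essential-unidimensionality verdict against the conventional cutoffs."""
        return self.ecv >= self.ecv_cutoff and self.omega_h >= self.omega_h_cutoff


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= 1e-8:
        return R
    vals = np.clip(vals, 1e-6, None)
    R2 = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def bifactor_indices(
    data: ResponseMatrix | pd.DataFrame | np.ndarray,
    n_specific: int = 3,
    loadings: tuple[np.ndarray, np.ndarray] | None = None,
    item_ids: list[str] | None = None,
) -> DimensionalityResult:
    """ECV and omega-hierarchical from an exploratory bifactor decomposition.

    ``data`` is a response matrix (polychoric correlations are computed) or a
    correlation matrix.  The pipeline is minres EFA with ``n_specific``
    factors, promax rotation, then a Schmid–Leiman transform through a
    one-factor solution of the factor correlations.  Alternatively pass
    ``loadings=(general, specific)`` to compute the indices directly.

        ECV     = sum(l_g^2) / (sum(l_g^2) + sum(l_s^2))
        omega_H = (sum l_g)^2 / model-implied total-score variance
    """
    if loadings is not None:
        lg = np.asarray(loadings[0], dtype=float)
        ls = np.atleast_2d(np.asarray(loadings[1], dtype=float))
        if ls.shape[0] != lg.shape[0]:
            ls = ls.T
        psi = np.clip(1.0 - lg**2 - (ls**2).sum(axis=1), 0.0, None)
    else:
        if isinstance(data, ResponseMatrix):
            R = polychoric_matrix(data).to_numpy()
            item_ids = item_ids or data.items
        else:
            arr = np.asarray(data, dtype=float)
            if arr.shape[0] == arr.shape[1] and np.allclose(np.diag(arr), 1.0):
                R = arr
            else:
                R = np.corrcoef(arr, rowvar=False)
        R = _nearest_psd(R)
        m = R.shape[0]
        if n_specific < 1 or n_specific >= m:
            raise ValidationError("n_specific must be in [1, n_items)")
        L1 = _minres_efa(R, n_specific)
        # drop negligible factors before rotation: rotating noise factors
        # leaks general variance into spurious specifics (over-extraction)
        ss = (L1**2).sum(axis=0)
        keep = ss >= max(0.1 * ss.max(), 0.2)
        L1 = L1[:, keep]
        n_specific = int(keep.sum())
        if n_specific == 1:
            lg = np.abs(L1[:, 0])
            ls = np.zeros((m, 1))
        else:
            pattern, phi = _promax(L1)
            # Schmid–Leiman: general factor of the factor correlations
            gload = _minres_efa(_nearest_psd(phi), 1)[:, 0]
            if gload.sum() < 0:
                gload = -gload
            lg = pattern @ gload
            if lg.sum() < 0:
                lg, pattern = -lg, -pattern
            ls = pattern * np.sqrt(np.clip(1.0 - gload**2, 0.0, None))[None, :]
        psi = np.clip(1.0 - lg**2 - (ls**2).sum(axis=1), 0.0, None)

    sum_lg2 = float(np.sum(lg**2))
    sum_ls2 = float(np.sum(ls**2))
    ecv = sum_lg2 / (sum_lg2 + sum_ls2) if (sum_lg2 + sum_ls2) > 0 else float("nan")
    total_var = float(np.sum(lg) ** 2 + np.sum(ls.sum(axis=0) ** 2) + np.sum(psi))
    omega_h = float(np.sum(lg) ** 2 / total_var) if total_var > 0 else float("nan")
    ids = item_ids or [f"I{i + 1:02d}" for i in range(len(lg))]
    return DimensionalityResult(
        general_loadings=pd.Series(lg, index=ids, name="lambda_g"),
        specific_loadings=pd.DataFrame(
            ls, index=ids, columns=[f"S{j + 1}" for j in range(ls.shape[1])]
        ),
        ecv=float(np.clip(ecv, 0.0, 1.0)),
        omega_h=float(np.clip(omega_h, 0.0, 1.0)),
    )
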