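"""Proportional-odds (cumulative logit) regression, pseudo-R² and p-value
adjustment — the inferential substrate of the DIF tests.

The model for an ordinal outcome y in 0..K-1 with covariates x is

    P(y <= k | x) = logistic(alpha_k - x' beta),   alpha_0 < ... < alpha_{K-2},

fit by maximum likelihood (L-BFGS on the exact negative log-likelihood with
analytic gradient; the cuts are kept ordered through a log-difference
reparametrization).  statsmodels' generic ``OrderedModel`` maximizes the
same likelihood and serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .data import ValidationError

__all__ = [
    "ProportionalOdds",
    "ProportionalOddsResults",
    "fit_proportional_odds",
    "pseudo_r2",
    "multiplicity_adjust",
]


class SeparationError(RuntimeError):
    """Quasi-complete separation: the MLE diverges."""


def _nll_grad(t, y_onehot_idx, X, K):
    """Exact negative log-likelihood and gradient.

    Parameter vector t = [alpha_0, log(alpha_1-alpha_0), ..., beta].
    """
    n, p = X.shape
    cuts = t[0] + np.concatenate(
        [[0.0], np.cumsum(np.exp(np.minimum(t[1 : K - 1], 30.0)))]
    )
    beta = t[K - 1 :]
    eta = X @ beta if p else np.zeros(n)
    # F[k] = P(y <= k), k = 0..K-2
    Z = cuts[None, :] - eta[:, None]  # (n, K-1)
    F = expit(Z)
    f = F * (1.0 - F)
    y = y_onehot_idx
    Fk = np.concatenate([F, np.ones((n, 1))], axis=1)  # P(y <= k) incl. K-1
    Fkm1 = np.concatenate([np.zeros((n, 1)), F], axis=1)
    Pk = Fk[np.arange(n), y] - Fkm1[np.arange(n), y]
    Pk = np.clip(Pk, 1e-300, None)
    nll = -float(np.sum(np.log(Pk)))

    # dP/dcut_j: +f_j if j == y, -f_j if j == y-1
    w_hi = np.zeros((n, K - 1))
    w_lo = np.zeros((n, K - 1))
    hi = y <= K - 2
    w_hi[np.flatnonzero(hi), y[hi]] = 1.0
    lo = y >= 1
    w_lo[np.flatnonzero(lo), y[lo] - 1] = 1.0
    dP_dcut = (w_hi - w_lo) * f  # (n, K-1)
    g_cut = -(dP_dcut / Pk[:, None]).sum(axis=0)
    # chain rule for the log-difference parametrization
    grad = np.empty_like(t)
    grad[0] = g_cut.sum()
    rev = np.cumsum(g_cut[::-1])[::-1]
    grad[1 : K - 1] = np.exp(np.minimum(t[1 : K - 1], 30.0)) * rev[1:]
    if p:
        # d eta enters with opposite sign to the cuts
        dP_deta = -dP_dcut.sum(axis=1)
        grad[K - 1 :] = -X.T @ (dP_deta / Pk)
    return nll, grad


@dataclass
class ProportionalOddsResults:
    """ML fit of a cumulative-logit model."""

    params: pd.Series  # cuts then slopes, named
    llf: float
    n: int
    k_categories: int
    converged: bool
    exog_names: list

    @property
    def cuts(self) -> np.ndarray:
        return self.params.iloc[: self.k_categories - 1].to_numpy()

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def summary(self) -> str:
        return (
            f"Proportional-odds model  n={self.n}  K={self.k_categories}  "
            f"llf={self.llf:.4f}\n" + self.params.to_string()
        )


class ProportionalOdds:
    """Cumulative-logit ordinal regression model.

    Parameters
    ----------
    endog : array of int
        Ordinal outcome; recoded to contiguous 0-based categories.
    exog : DataFrame or 2-D array, optional
        Covariates (no intercept column; the cuts play that role).
    """

    def __init__(self, endog, exog=None):
        y = np.asarray(endog)
        if np.any(pd.isna(y)):
            raise ValidationError("endog contains missing values")
        y = y.astype(int)
        levels = np.unique(y)
        if levels.size < 2:
            raise ValidationError("endog must have >= 2 observed categories")
        self._recode = {v: i for i, v in enumerate(levels)}
        self.y = np.vectorize(self._recode.get)(y)
        self.K = levels.size
        if exog is None:
            self.X = np.empty((len(y), 0))
            self.exog_names = []
        else:
            if isinstance(exog, pd.DataFrame):
                self.exog_names = [str(c) for c in exog.columns]
                self.X = exog.to_numpy(dtype=float)
            else:
                self.X = np.atleast_2d(np.asarray(exog, dtype=float))
                if self.X.shape[0] != len(y):
                    self.X = self.X.T
                self.exog_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
            if np.any(~np.isfinite(self.X)):
                raise ValidationError("exog contains non-finite values")
            if self.X.shape[1]:
                rank = np.linalg.matrix_rank(self.X - self.X.mean(axis=0))
                ncol = self.X.shape[1]
                if rank < ncol:
                    # name the offending columns via QR pivoting
                    from scipy.linalg import qr as _qr

                    _, _, piv = _qr(self.X - self.X.mean(axis=0), pivoting=True)
                    bad = [self.exog_names[j] for j in piv[rank:]]
                    raise ValidationError(
                        f"design matrix is rank deficient; collinear column(s): {bad}"
                    )

    def fit(self, max_beta: float = 15.0) -> ProportionalOddsResults:
        n = len(self.y)
        K = self.K
        counts = np.bincount(self.y, minlength=K).astype(float)
        cum = np.cumsum(counts)[:-1] / n
        cuts0 = np.log(cum / (1 - cum))
        cuts0 = np.maximum.accumulate(cuts0) + np.arange(K - 1) * 1e-6
        t0 = np.concatenate(
            [[cuts0[0]], np.log(np.maximum(np.diff(cuts0), 1e-6)), np.zeros(self.X.shape[1])]
        )
        res = minimize(
            _nll_grad, t0, args=(self.y, self.X, K), jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        t = res.x
        cuts = t[0] + np.concatenate(
            [[0.0], np.cumsum(np.exp(np.minimum(t[1 : K - 1], 30.0)))]
        )
        beta = t[K - 1 :]
        if np.any(np.abs(beta) > max_beta) or np.any(np.abs(cuts) > 3 * max_beta):
            raise SeparationError(
                "coefficient diverged (|beta| > "
                f"{max_beta}); data are (quasi-)separated"
            )
        names = [f"cut_{k + 1}" for k in range(K - 1)] + self.exog_names
        params = pd.Series(np.concatenate([cuts, beta]), index=names)
        return ProportionalOddsResults(
            params=params,
            llf=-float(res.fun),
            n=n,
            k_categories=K,
            converged=bool(res.success),
            exog_names=self.exog_names,
        )


def fit_proportional_odds(y, design=None) -> ProportionalOddsResults:
    """Functional wrapper around :class:`ProportionalOdds`."""
    return ProportionalOdds(y, design).fit()


def pseudo_r2(fit_null: ProportionalOddsResults, fit_full: ProportionalOddsResults):
    """Cox–Snell, Nagelkerke and McFadden pseudo-R² between nested fits.

    CS = 1 - exp(2 (L0 - L1)/n);  N = CS / (1 - exp(2 L0 / n));  McF = 1 - L1/L0.
    """
    if fit_null.n != fit_full.n:
        raise ValidationError("pseudo_r2 requires fits on identical data")
    L0, L1, n = fit_null.llf, fit_full.llf, fit_null.n
    if L1 < L0 - 1e-6:
        raise ValidationError(
            f"full-model likelihood below null ({L1:.6f} < {L0:.6f}): nesting violated"
        )
    L1 = max(L1, L0)
    cs = 1.0 - np.exp(2.0 * (L0 - L1) / n)
    nk = cs / (1.0 - np.exp(2.0 * L0 / n))
    mcf = 1.0 - L1 / L0 if L0 != 0 else 0.0
    return float(cs), float(nk), float(mcf)


def multiplicity_adjust(p_values, method: str = "none") -> np.ndarray:
    """Adjust per-item p-values: 'none', 'bonferroni' or 'benjamini_hochberg'."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "benjamini_hochberg":
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValidationError(f"unknown adjustment method {method!r}")
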