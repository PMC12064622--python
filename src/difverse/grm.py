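"""Graded response model: probabilities, marginal-ML estimation, EAP scoring.

The graded response model (GRM) for an item with ordered categories
0..K-1 puts logistic curves on the cumulative probabilities,

    P(X >= k | theta) = 1 / (1 + exp(-D * a * (theta - b_k))),   k = 1..K-1,

with one discrimination ``a`` per item and strictly increasing thresholds
``b_k``.  Estimation is marginal maximum likelihood via EM on a fixed
quadrature grid; the latent metric is identified by theta ~ N(0, 1) in the
(reference) group.  T-scores are the affine rescaling 50 + 10*theta.

Model classes follow the statsmodels convention: construct from data, call
``fit()``, get a results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .data import (
    GroupDistribution,
    ItemParameters,
    ItemParameterSet,
    ResponseMatrix,
    StudyFrame,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "category_response_prob",
    "eap_score",
    "test_characteristic_curve",
    "test_information",
    "GradedResponseModel",
    "MultigroupGRM",
    "GRMResults",
    "ConvergenceError",
]

_EM_GRID = np.linspace(-6.0, 6.0, 61)  # estimation grid
_EAP_GRID = np.linspace(-8.0, 8.0, 401)  # scoring grid (finer: posterior sds are small)
_TINY = 1e-300


class ConvergenceError(RuntimeError):
    """EM did not converge; ``last_result`` carries the final iterate."""

    def __init__(self, message: str, last_result: "GRMResults | None" = None):
        super().__init__(message)
        self.last_result = last_result


# ---------------------------------------------------------------------------
# probability machinery


def _cumulative_probs(a: float, b: np.ndarray, theta: np.ndarray, D: float) -> np.ndarray:
    """P(X >= k) for k = 1..K-1; shape (K-1, len(theta))."""
    return expit(D * a * (theta[None, :] - np.asarray(b, float)[:, None]))


def category_response_prob(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """Category probabilities P(X = k | theta) for one item.

    Parameters
    ----------
    item : ItemParameters
        Discrimination and ordered thresholds.
    theta : float or array
        Latent-trait value(s); finite.
    D : float
        Logistic scaling constant of the metric the parameters live on.

    Returns
    -------
    ndarray
        Shape (K,) for scalar theta, else (len(theta), K); rows sum to 1.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(th)):
        raise ValidationError("theta must be finite")
    S = _cumulative_probs(item.a, np.asarray(item.b), th, D)  # (K-1, Q)
    K = len(item.b) + 1
    P = np.empty((K, th.size))
    P[0] = 1.0 - S[0]
    P[1:-1] = S[:-1] - S[1:]
    P[-1] = S[-1]
    P = P.T
    return P[0] if np.isscalar(theta) or np.ndim(theta) == 0 else P


def _log_prob_table(a: float, b: np.ndarray, nodes: np.ndarray, D: float) -> np.ndarray:
    """log P(X = k | node) table, shape (K, Q)."""
    S = _cumulative_probs(a, b, nodes, D)
    K = len(b) + 1
    P = np.empty((K, nodes.size))
    P[0] = 1.0 - S[0]
    P[1:-1] = S[:-1] - S[1:]
    P[-1] = S[-1]
    return np.log(np.clip(P, _TINY, None))


def expected_item_score(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """Item characteristic curve on the expected-score metric: E[X | theta]."""
    P = np.atleast_2d(category_response_prob(item, np.atleast_1d(theta), D))
    k = np.arange(P.shape[1])
    out = P @ k
    return out if np.ndim(theta) else float(out[0])


def item_information(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """Fisher information of one item at theta (sums to the test information)."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.b)
    S = _cumulative_probs(item.a, b, th, D)  # (K-1, Q)
    s = S * (1.0 - S)
    K = len(b) + 1
    P = np.empty((K, th.size))
    P[0] = 1.0 - S[0]
    P[1:-1] = S[:-1] - S[1:]
    P[-1] = S[-1]
    dP = np.empty_like(P)  # P'_k = D a (s_k - s_{k+1}), s_0 = s_K = 0
    dP[0] = -D * item.a * s[0]
    dP[1:-1] = D * item.a * (s[:-1] - s[1:])
    dP[-1] = D * item.a * s[-1]
    info = np.sum(dP**2 / np.clip(P, _TINY, None), axis=0)
    return info if np.ndim(theta) else float(info[0])


# ---------------------------------------------------------------------------
# scoring


def eap_score(
    responses: ResponseMatrix | pd.DataFrame,
    params: ItemParameterSet,
    prior: GroupDistribution | tuple[float, float] = (0.0, 1.0),
    study: StudyFrame | None = None,
    priors: dict[str, GroupDistribution] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Expected-a-posteriori trait estimates with posterior sds and T-scores.

    With ``study`` (and optionally per-group ``priors``), each person is
    scored under the parameter records and normal prior applicable to their
    group — the scoring rule used for partially invariant models.  Persons
    with no observed responses get the prior mean/sd back.

    Returns a DataFrame indexed by person with columns theta, se, t_score.
    """
    if isinstance(responses, pd.DataFrame):
        responses = ResponseMatrix(responses)
    nodes = _EAP_GRID if grid is None else np.asarray(grid, dtype=float)
    X = responses.values
    n = len(X)
    loglik = np.zeros((n, nodes.size))
    if study is None:
        group_of = pd.Series(["__all__"] * n, index=X.index)
        if isinstance(prior, tuple):
            prior = GroupDistribution("__all__", *prior)
        priors = {"__all__": prior}
        param_maps = {"__all__": params.for_group(None)}
    else:
        _, study = study.align(responses)
        group_of = study.group_of()
        if priors is None:
            priors = {g: GroupDistribution(g, 0.0, 1.0) for g in study.groups}
        param_maps = {g: params.for_group(g if params.groups else None) for g in study.groups}

    theta = np.empty(n)
    se = np.empty(n)
    garr = group_of.to_numpy()
    for g in dict.fromkeys(garr):
        mask = garr == g
        pm = param_maps[g]
        ll = np.zeros((int(mask.sum()), nodes.size))
        for item in responses.items:
            x = X.loc[mask, item].to_numpy()
            obs = ~np.isnan(x)
            if not obs.any():
                continue
            tab = _log_prob_table(pm[item].a, np.asarray(pm[item].b), nodes, params.D)
            ll[obs] += tab[x[obs].astype(int)]
        pr = priors[g]
        logw = norm.logpdf(nodes, pr.mean, pr.sd)
        post = ll + logw[None, :]
        post -= post.max(axis=1, keepdims=True)
        w = np.exp(post)
        w /= w.sum(axis=1, keepdims=True)
        m1 = w @ nodes
        m2 = w @ nodes**2
        theta[mask] = m1
        se[mask] = np.sqrt(np.maximum(m2 - m1**2, 0.0))
        loglik[mask] = ll
    out = pd.DataFrame(
        {"theta": theta, "se": se, "t_score": 50.0 + 10.0 * theta}, index=X.index
    )
    out.index.name = "person_id"
    return out


# ---------------------------------------------------------------------------
# test-level curves


def _resolve_groups(params: ItemParameterSet, groups) -> list[str | None]:
    if groups is None:
        groups = params.groups or [None]
    return list(groups)


def test_characteristic_curve(
    params: ItemParameterSet,
    theta_grid,
    groups=None,
    items: list[str] | None = None,
) -> pd.DataFrame:
    """Expected total score at each theta, per group (tidy long format)."""
    th = np.asarray(theta_grid, dtype=float)
    rows = []
    item_sets = []
    for g in _resolve_groups(params, groups):
        pm = params.for_group(g)
        use = items if items is not None else list(pm)
        item_sets.append(tuple(sorted(use)))
        total = np.zeros_like(th)
        for it in use:
            total += expected_item_score(pm[it], th, params.D)
        rows.append(
            pd.DataFrame(
                {"group": "all" if g is None else g, "theta": th, "expected_score": total}
            )
        )
    if len(set(item_sets)) > 1:
        raise ValidationError("groups do not share a common item set")
    return pd.concat(rows, ignore_index=True)


def test_information(
    params: ItemParameterSet, theta_grid, group: str | None = None
) -> pd.DataFrame:
    """Item and total Fisher information over a theta grid (tidy long format)."""
    th = np.asarray(theta_grid, dtype=float)
    pm = params.for_group(group)
    rows = [
        pd.DataFrame({"item_id": it, "theta": th, "information": item_information(p, th, params.D)})
        for it, p in pm.items()
    ]
    out = pd.concat(rows, ignore_index=True)
    total = out.groupby("theta", sort=False)["information"].sum().reset_index()
    total.insert(0, "item_id", "__total__")
    return pd.concat([out, total], ignore_index=True)


# ---------------------------------------------------------------------------
# estimation


def _collapse_map(col: np.ndarray, k: int, item: str) -> tuple[np.ndarray, dict[int, int]]:
    """Map sparse categories onto contiguous 0-based codes.

    Unobserved categories are merged with the adjacent lower observed
    category (category 0, if nothing lower is observed).  Returns the recoded
    column and the old->new map.
    """
    obs = col[~np.isnan(col)].astype(int)
    present = np.zeros(k, dtype=bool)
    present[np.unique(obs)] = True
    if present.sum() < 2:
        raise ValidationError(f"item {item!r}: fewer than 2 observed categories")
    new_code = np.cumsum(present) - 1
    new_code = np.maximum(new_code, 0)
    mapping = {old: int(new_code[old]) for old in range(k)}
    recoded = col.copy()
    m = ~np.isnan(col)
    recoded[m] = new_code[col[m].astype(int)]
    if present.sum() < k:
        logger.info("item %s: collapsed %d empty categories", item, k - int(present.sum()))
    return recoded, mapping


def _start_values(col: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """a = 1; thresholds from normal quantiles of cumulative proportions."""
    obs = col[~np.isnan(col)].astype(int)
    counts = np.bincount(obs, minlength=k).astype(float)
    p_ge = 1.0 - np.cumsum(counts)[:-1] / counts.sum()
    p_ge = np.clip(p_ge, 1e-3, 1 - 1e-3)
    b = -norm.ppf(p_ge)
    b = np.maximum.accumulate(b)
    b += np.arange(k - 1) * 1e-3  # break exact ties
    return 1.0, b


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    d = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.maximum(d, 1e-8))])


def _unpack(t: np.ndarray) -> tuple[float, np.ndarray]:
    # exponents clipped: keeps exploratory L-BFGS steps finite
    a = float(np.exp(min(t[0], 30.0)))
    b = t[1] + np.concatenate([[0.0], np.cumsum(np.exp(np.minimum(t[2:], 30.0)))])
    return a, b


def _item_nll_grad(t: np.ndarray, r: np.ndarray, nodes: np.ndarray, D: float):
    """Expected complete-data negative log-likelihood of one item + gradient.

    ``r`` is the (K, Q) table of expected response counts per category and
    quadrature node accumulated in the E-step.
    """
    a, b = _unpack(t)
    S = _cumulative_probs(a, b, nodes, D)  # (K-1, Q)
    K = r.shape[0]
    P = np.empty((K, nodes.size))
    P[0] = 1.0 - S[0]
    P[1:-1] = S[:-1] - S[1:]
    P[-1] = S[-1]
    Pc = np.clip(P, _TINY, None)
    nll = -float(np.sum(r * np.log(Pc)))
    # dNLL/dS_j = -(r_j / P_j - r_{j-1} / P_{j-1})   (S_j enters P_j +, P_{j-1} -)
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = r / Pc
        dS = -(ratio[1:] - ratio[:-1])  # (K-1, Q)
        sprime = S * (1.0 - S)
        ga = float(np.sum(dS * D * (nodes[None, :] - b[:, None]) * sprime))
        gb = np.sum(dS * (-D * a) * sprime, axis=1)  # (K-1,)
        grad = np.empty_like(t)
        grad[0] = ga * a
        grad[1] = gb.sum()
        csum = np.cumsum(gb[::-1])[::-1]  # sum_{j >= l} gb_j
        grad[2:] = np.exp(np.minimum(t[2:], 30.0)) * csum[1:]
    # huge exploratory steps can overflow; a bounded gradient keeps L-BFGS sane
    return nll, np.nan_to_num(grad, posinf=1e12, neginf=-1e12)


def _maximize_item(r: np.ndarray, nodes: np.ndarray, D: float, t0: np.ndarray) -> np.ndarray:
    res = minimize(
        _item_nll_grad, t0, args=(r, nodes, D), jac=True, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res.x


@dataclass
class GRMResults:
    """Fitted graded response model.

    Attributes
    ----------
    params : ItemParameterSet
        Estimated item parameters (shared across groups except any freed
        items in a partial-invariance fit).
    group_distributions : dict[str, GroupDistribution]
        Latent mean/sd per group; reference fixed at (0, 1).
    llf : float
        Final marginal log-likelihood.
    llf_history : list[float]
        Marginal log-likelihood per EM cycle (non-decreasing).
    """

    params: ItemParameterSet
    group_distributions: dict[str, GroupDistribution]
    llf: float
    llf_history: list
    n_cycles: int
    converged: bool
    collapse_maps: dict
    n_obs: int

    def summary(self) -> str:
        lines = [
            "Graded Response Model (marginal ML, EM)",
            f"  persons: {self.n_obs}   items: {len(self.params.item_ids)}",
            f"  log-likelihood: {self.llf:.3f}   cycles: {self.n_cycles}"
            f"   converged: {self.converged}",
            "  group distributions:",
        ]
        for g, d in self.group_distributions.items():
            lines.append(f"    {g}: mean={d.mean:+.3f} sd={d.sd:.3f}")
        lines.append(self.params.to_frame().to_string(index=False))
        return "\n".join(lines)

    def score(self, responses, study=None, grid=None) -> pd.DataFrame:
        """EAP-score persons under this calibration (group priors applied)."""
        priors = None
        if study is not None:
            priors = {g: self.group_distributions.get(g, GroupDistribution(g)) for g in study.groups}
        return eap_score(responses, self.params, study=study, priors=priors, grid=grid)


class MultigroupGRM:
    """Multigroup graded response model with optional partial invariance.

    Item parameters are constrained equal across groups except those in
    ``free_items``, which get one record per group.  The reference group's
    latent distribution is fixed at N(0, 1); other groups' means and sds are
    estimated, which is what identifies cross-group comparisons.
    """

    def __init__(
        self,
        responses: ResponseMatrix,
        study: StudyFrame,
        reference_group: str | None = None,
        free_items: tuple[str, ...] = (),
        D: float = 1.0,
    ):
        responses, study = study.align(responses)
        self.responses = responses
        self.study = study
        self.groups = study.groups
        if not self.groups:
            raise ValidationError("no groups present")
        for g in self.groups:
            n_g = int((study.group_of() == g).sum())
            if n_g == 0:
                raise ValidationError(f"empty group {g!r}")
            if n_g < 50:
                logger.warning("group %s has only %d persons", g, n_g)
        self.reference_group = reference_group or self.groups[0]
        if self.reference_group not in self.groups:
            raise ValidationError(f"reference group {self.reference_group!r} not present")
        free = tuple(free_items)
        unknown = [i for i in free if i not in responses.items]
        if unknown:
            raise ValidationError(f"free_items not in the response matrix: {unknown}")
        if free and len(free) >= len(responses.items):
            raise ValidationError("free_items must leave at least one anchor item")
        self.free_items = free
        self.D = float(D)

    def fit(self, max_cycles: int = 500, tol: float = 1e-4) -> GRMResults:
        X = self.responses.values
        items = self.responses.items
        n = len(X)
        nodes = _EM_GRID
        Q = nodes.size
        garr = self.study.group_of().to_numpy()
        gidx = {g: np.flatnonzero(garr == g) for g in self.groups}

        # recode sparse categories once, on the pooled subset
        cols: dict[str, np.ndarray] = {}
        kcat: dict[str, int] = {}
        collapse: dict[str, dict] = {}
        for it in items:
            col = X[it].to_numpy(dtype=float)
            if not np.any(~np.isnan(col)):
                raise ValidationError(f"item {it!r}: no observed responses")
            rec, cmap = _collapse_map(col, self.responses.n_categories[it], it)
            cols[it] = rec
            kcat[it] = int(np.nanmax(rec)) + 1
            if any(o != v for o, v in cmap.items()):
                collapse[it] = cmap

        # parameter blocks: (item, None) shared, or (item, group) if freed
        blocks: dict[tuple, tuple[float, np.ndarray]] = {}
        for it in items:
            a0, b0 = _start_values(cols[it], kcat[it])
            if it in self.free_items:
                for g in self.groups:
                    blocks[(it, g)] = (a0, b0.copy())
            else:
                blocks[(it, None)] = (a0, b0.copy())
        mu = {g: 0.0 for g in self.groups}
        sd = {g: 1.0 for g in self.groups}

        obs_mask = {it: ~np.isnan(cols[it]) for it in items}
        obs_codes = {it: np.where(obs_mask[it], cols[it], 0).astype(int) for it in items}

        llf_history: list[float] = []
        converged = False
        n_cycles = 0
        for cycle in range(max_cycles):
            n_cycles = cycle + 1
            # E-step: person x node log-likelihood
            ll = np.zeros((n, Q))
            tabs: dict[tuple, np.ndarray] = {}
            for key, (a, b) in blocks.items():
                tabs[key] = _log_prob_table(a, b, nodes, self.D)
            for it in items:
                m = obs_mask[it]
                code = obs_codes[it]
                if it in self.free_items:
                    for g in self.groups:
                        idx = gidx[g]
                        mi = idx[m[idx]]
                        ll[mi] += tabs[(it, g)][code[mi], :]
                else:
                    tab = tabs[(it, None)]
                    ll[m] += tab[code[m], :]
            logw = np.empty((n, Q))
            for g in self.groups:
                logw[gidx[g]] = norm.logpdf(nodes, mu[g], sd[g]) - np.log(
                    norm.pdf(nodes, mu[g], sd[g]).sum()
                )
            post = ll + logw
            mx = post.max(axis=1, keepdims=True)
            w = np.exp(post - mx)
            tot = w.sum(axis=1, keepdims=True)
            llf = float(np.sum(np.log(tot) + mx))
            llf_history.append(llf)
            w /= tot

            # expected counts and M-step
            max_change = 0.0
            new_blocks: dict[tuple, tuple[float, np.ndarray]] = {}
            for key, (a, b) in blocks.items():
                it, g = key
                m = obs_mask[it]
                if g is not None:
                    sel = np.zeros(n, dtype=bool)
                    sel[gidx[g]] = True
                    m = m & sel
                code = obs_codes[it]
                K = kcat[it]
                r = np.zeros((K, Q))
                wm = w[m]
                cm = code[m]
                for k in range(K):
                    r[k] = wm[cm == k].sum(axis=0)
                t_new = _maximize_item(r, nodes, self.D, _pack(a, b))
                a_new, b_new = _unpack(t_new)
                max_change = max(
                    max_change, abs(a_new - a), float(np.max(np.abs(b_new - b)))
                )
                new_blocks[key] = (a_new, b_new)
            blocks = new_blocks
            for g in self.groups:
                if g == self.reference_group:
                    continue
                wg = w[gidx[g]]
                m1 = float((wg @ nodes).mean())
                m2 = float((wg @ nodes**2).mean())
                sd_new = float(np.sqrt(max(m2 - m1**2, 1e-6)))
                max_change = max(max_change, abs(m1 - mu[g]), abs(sd_new - sd[g]))
                mu[g], sd[g] = m1, sd_new

            if max_change < tol:
                converged = True
                break

        records = []
        for it in items:
            if it in self.free_items:
                for g in self.groups:
                    a, b = blocks[(it, g)]
                    records.append(ItemParameters(it, a, tuple(b), g))
            else:
                a, b = blocks[(it, None)]
                records.append(ItemParameters(it, a, tuple(b), None))
        result = GRMResults(
            params=ItemParameterSet(records, D=self.D),
            group_distributions={
                g: GroupDistribution(g, mu[g], sd[g]) for g in self.groups
            },
            llf=llf_history[-1],
            llf_history=llf_history,
            n_cycles=n_cycles,
            converged=converged,
            collapse_maps=collapse,
            n_obs=n,
        )
        if not converged:
            raise ConvergenceError(
                f"EM did not converge in {n_cycles} cycles "
                f"(last max parameter change >= {tol})",
                last_result=result,
            )
        return result


class GradedResponseModel(MultigroupGRM):
    """Single-group GRM: marginal ML with theta ~ N(0, 1)."""

    def __init__(self, responses: ResponseMatrix, D: float = 1.0):
        study = StudyFrame(
            pd.DataFrame({"group": ["__all__"] * len(responses)}, index=responses.persons)
        )
        super().__init__(responses, study, reference_group="__all__", D=D)

    def fit(self, max_cycles: int = 500, tol: float = 1e-4) -> GRMResults:
        res = super().fit(max_cycles=max_cycles, tol=tol)
        res.group_distributions = {}
        return res


def fit_grm(responses: ResponseMatrix, D: float = 1.0, **kw) -> GRMResults:
    """Functional wrapper: single-group marginal-ML GRM fit."""
    return GradedResponseModel(responses, D=D).fit(**kw)


def fit_multigroup_grm(
    responses: ResponseMatrix,
    study: StudyFrame,
    reference_group: str | None = None,
    D: float = 1.0,
    **kw,
) -> GRMResults:
    """Functional wrapper: multigroup GRM, shared items, free group moments."""
    return MultigroupGRM(responses, study, reference_group=reference_group, D=D).fit(**kw)
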