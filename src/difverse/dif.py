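"""Per-item DIF statistics from nested proportional-odds models.

For each item, three cumulative-logit models are fit on the IRT trait
estimate theta:

    M1:  item ~ theta                (+ age + age x group when age-adjusted)
    M2:  M1 + group
    M3:  M2 + theta x group

A group main effect (M1 vs M2) indicates uniform DIF; the trait-by-group
interaction (M2 vs M3) indicates non-uniform DIF.  Flagging criteria follow
the ordinal-logistic DIF (lordif) tradition: likelihood-ratio tests (raw,
Bonferroni- or Benjamini–Hochberg-adjusted) on the total M1-vs-M3 test,
pseudo-R² change between M1 and M3, and the relative change in the theta
coefficient between M1 and M2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import ValidationError
from .ordinal import (
    ProportionalOdds,
    SeparationError,
    multiplicity_adjust,
    pseudo_r2,
)

__all__ = ["DIFItemResult", "dif_statistics_item", "flag_items", "CRITERIA"]

#: criterion name -> threshold set used in the canonical grid
CRITERIA = {
    "lrt": (0.02, 0.05),
    "lrt_bonferroni": (0.02, 0.05),
    "lrt_bh": (0.02, 0.05),
    "beta": (0.01, 0.05),
    "r2_coxsnell": (0.02, 0.03, 0.05),
    "r2_nagelkerke": (0.02, 0.03, 0.05),
    "r2_mcfadden": (0.02, 0.03, 0.05),
}
LRT_CRITERIA = ("lrt", "lrt_bonferroni", "lrt_bh")


@dataclass
class DIFItemResult:
    """All DIF statistics of one item under one model configuration."""

    item_id: str
    n: int
    ll_m1: float
    ll_m2: float
    ll_m3: float
    chi2_uniform: float  # M1 vs M2
    df_uniform: int
    p_uniform: float
    chi2_nonuniform: float  # M2 vs M3
    df_nonuniform: int
    p_nonuniform: float
    chi2_total: float  # M1 vs M3
    df_total: int
    p_total: float
    delta_r2_coxsnell: float
    delta_r2_nagelkerke: float
    delta_r2_mcfadden: float
    beta_change: float
    valid: bool = True
    failure: str | None = None

    def as_row(self) -> dict:
        return {
            "item_id": self.item_id,
            "n": self.n,
            "ll_m1": self.ll_m1,
            "ll_m2": self.ll_m2,
            "ll_m3": self.ll_m3,
            "chi2_uniform": self.chi2_uniform,
            "p_uniform": self.p_uniform,
            "chi2_nonuniform": self.chi2_nonuniform,
            "p_nonuniform": self.p_nonuniform,
            "chi2_total": self.chi2_total,
            "df_total": self.df_total,
            "p_total": self.p_total,
            "delta_r2_coxsnell": self.delta_r2_coxsnell,
            "delta_r2_nagelkerke": self.delta_r2_nagelkerke,
            "delta_r2_mcfadden": self.delta_r2_mcfadden,
            "beta_change": self.beta_change,
            "valid": self.valid,
        }


def _invalid(item_id: str, n: int, reason: str) -> DIFItemResult:
    nan = float("nan")
    return DIFItemResult(
        item_id, n, nan, nan, nan, nan, 0, nan, nan, 0, nan, nan, 0, nan,
        nan, nan, nan, nan, valid=False, failure=reason,
    )


def dif_statistics_item(
    item_responses,
    thetas,
    group,
    age=None,
    adjust_age: bool = False,
    item_id: str | None = None,
    reference_group: str | None = None,
) -> DIFItemResult:
    """DIF statistics for one item.

    Parameters
    ----------
    item_responses : array of int (NaN allowed, dropped listwise)
    thetas : array of float
        Trait estimates computed under the analysis cell's parameter source.
    group : array of labels (>= 2 groups after listwise deletion)
    age : array of float, required when ``adjust_age``
    adjust_age : bool
        Adds age and age-x-group terms to all three models, so the DIF tests
        are conditional on age.
    """
    y = np.asarray(item_responses, dtype=float)
    th = np.asarray(thetas, dtype=float)
    g = np.asarray(group).astype(str)
    iid = item_id or "item"
    keep = ~np.isnan(y) & np.isfinite(th)
    if adjust_age:
        if age is None:
            raise ValidationError("adjust_age=True requires age")
        ag = np.asarray(age, dtype=float)
        keep &= np.isfinite(ag)
    y, th, g = y[keep], th[keep], g[keep]
    levels = list(dict.fromkeys(g))
    if reference_group is not None and reference_group in levels:
        levels = [reference_group] + [l for l in levels if l != reference_group]
    if len(levels) < 2:
        raise ValidationError(f"item {iid!r}: need >= 2 groups, got {levels}")
    n = int(keep.sum())

    dummies = {f"group[{l}]": (g == l).astype(float) for l in levels[1:]}
    base = {"theta": th}
    if adjust_age:
        ag = np.asarray(age, dtype=float)[keep]
        ag = (ag - ag.mean()) / (ag.std() or 1.0)
        base["age"] = ag
        for l in levels[1:]:
            base[f"age:group[{l}]"] = ag * (g == l)
    m1_cols = dict(base)
    m2_cols = dict(base, **dummies)
    m3_cols = dict(m2_cols)
    for l in levels[1:]:
        m3_cols[f"theta:group[{l}]"] = th * (g == l)

    try:
        f1 = ProportionalOdds(y.astype(int), pd.DataFrame(m1_cols)).fit()
        f2 = ProportionalOdds(y.astype(int), pd.DataFrame(m2_cols)).fit()
        f3 = ProportionalOdds(y.astype(int), pd.DataFrame(m3_cols)).fit()
    except (SeparationError, ValidationError) as exc:
        return _invalid(iid, n, str(exc))
    if not (f1.converged and f2.converged and f3.converged):
        return _invalid(iid, n, "optimizer reported non-convergence")

    df_u = len(levels) - 1
    df_n = len(levels) - 1
    c12 = max(0.0, 2.0 * (f2.llf - f1.llf))
    c23 = max(0.0, 2.0 * (f3.llf - f2.llf))
    c13 = max(0.0, 2.0 * (f3.llf - f1.llf))
    r2 = pseudo_r2(f1, f3)
    b1, b2 = f1.coef("theta"), f2.coef("theta")
    beta_change = abs(b2 - b1) / abs(b1) if b1 != 0 else float("inf")
    return DIFItemResult(
        item_id=iid,
        n=n,
        ll_m1=f1.llf,
        ll_m2=f2.llf,
        ll_m3=f3.llf,
        chi2_uniform=c12,
        df_uniform=df_u,
        p_uniform=float(chi2.sf(c12, df_u)),
        chi2_nonuniform=c23,
        df_nonuniform=df_n,
        p_nonuniform=float(chi2.sf(c23, df_n)),
        chi2_total=c13,
        df_total=df_u + df_n,
        p_total=float(chi2.sf(c13, df_u + df_n)),
        delta_r2_coxsnell=r2[0],
        delta_r2_nagelkerke=r2[1],
        delta_r2_mcfadden=r2[2],
        beta_change=beta_change,
    )


def flag_items(results, criterion: str, threshold: float) -> set[str]:
    """Items flagged for DIF under one criterion/threshold.

    LRT criteria flag when the (possibly multiplicity-adjusted) p-value of
    the total M1-vs-M3 test falls below the threshold; the beta criterion
    flags when the relative theta-coefficient change is at least the
    threshold; R² criteria flag when the named pseudo-R² change is at least
    the threshold.  Invalid (non-converged) items are never flagged.
    """
    if criterion not in CRITERIA:
        raise ValidationError(f"unknown criterion {criterion!r}")
    results = [r for r in results if r.valid]
    if not results:
        return set()
    if criterion in LRT_CRITERIA:
        method = {
            "lrt": "none",
            "lrt_bonferroni": "bonferroni",
            "lrt_bh": "benjamini_hochberg",
        }[criterion]
        p = multiplicity_adjust([r.p_total for r in results], method)
        return {r.item_id for r, pv in zip(results, p) if pv < threshold}
    if criterion == "beta":
        return {r.item_id for r in results if r.beta_change >= threshold}
    attr = {
        "r2_coxsnell": "delta_r2_coxsnell",
        "r2_nagelkerke": "delta_r2_nagelkerke",
        "r2_mcfadden": "delta_r2_mcfadden",
    }[criterion]
    return {r.item_id for r in results if getattr(r, attr) >= threshold}
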