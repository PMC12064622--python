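"""Synthetic multi-group GRM data with controllable differential item functioning.

The generator draws an item bank, optionally perturbs it for a focal group
(uniform DIF = threshold shift, non-uniform DIF = slope change), draws group
trait distributions with an age covariate correlated to the trait, and
samples ordinal responses by inverse-CDF from the model's category
probabilities.  ``make_study_fixture`` builds the default three-country
study: 1600 / 1000 / 1001 persons with the published demographic margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .data import (
    GroupDistribution,
    ItemParameters,
    ItemParameterSet,
    ResponseMatrix,
    StudyFrame,
    ValidationError,
)
from .grm import category_response_prob

__all__ = [
    "GroupSpec",
    "DIFSpec",
    "SimulationConfig",
    "simulate_item_bank",
    "inject_dif",
    "simulate_responses",
    "make_study_fixture",
    "StudyFixture",
]


@dataclass(frozen=True)
class GroupSpec:
    """Sampling recipe for one group."""

    label: str
    n: int
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    age_mean: float = 45.0
    age_sd: float = 15.0
    age_range: tuple[float, float] = (18.0, 88.0)
    theta_age_corr: float = -0.2

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"group {self.label!r}: n must be >= 1")


@dataclass(frozen=True)
class DIFSpec:
    """One injected DIF effect.

    ``uniform`` shifts every threshold of ``item`` by ``magnitude`` for
    ``group``; ``nonuniform`` multiplies the discrimination by
    (1 + magnitude).
    """

    item: str
    group: str
    kind: str  # "uniform" | "nonuniform"
    magnitude: float

    def __post_init__(self):
        if self.kind not in ("uniform", "nonuniform"):
            raise ValidationError(f"unknown DIF kind {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise ValidationError("DIF magnitude must be finite")


@dataclass(frozen=True)
class SimulationConfig:
    n_items: int = 35
    n_categories: int = 5
    a_range: tuple[float, float] = (1.0, 2.5)
    b_range: tuple[float, float] = (-2.0, 2.0)
    groups: tuple[GroupSpec, ...] = (GroupSpec("G1", 500),)
    dif: tuple[DIFSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_items < 1 or self.n_categories < 2:
            raise ValidationError("need >= 1 item and >= 2 categories")
        if self.a_range[0] <= 0 or self.a_range[1] < self.a_range[0]:
            raise ValidationError("invalid discrimination range")
        if self.b_range[1] <= self.b_range[0]:
            raise ValidationError("invalid threshold range")


def simulate_item_bank(config: SimulationConfig) -> ItemParameterSet:
    """Draw a GRM item bank: a ~ U(a_range), thresholds sorted U(b_range)."""
    rng = np.random.default_rng(config.seed)
    recs = []
    for i in range(config.n_items):
        a = rng.uniform(*config.a_range)
        b = np.sort(rng.uniform(*config.b_range, size=config.n_categories - 1))
        while np.any(np.diff(b) < 0.05):  # keep thresholds separated
            b = np.sort(rng.uniform(*config.b_range, size=config.n_categories - 1))
        recs.append(ItemParameters(f"I{i + 1:02d}", a, tuple(b)))
    return ItemParameterSet(recs)


def inject_dif(params: ItemParameterSet, dif: tuple[DIFSpec, ...]) -> ItemParameterSet:
    """Add group-specific records realizing the requested DIF effects."""
    recs = params.records
    by_id = {r.item_id: r for r in recs if r.group is None}
    for spec in dif:
        if spec.item not in by_id:
            raise ValidationError(f"DIF target {spec.item!r} not in the bank")
        base = by_id[spec.item]
        if spec.kind == "uniform":
            new = replace(
                base, b=tuple(np.asarray(base.b) + spec.magnitude), group=spec.group
            )
        else:
            a_new = base.a * (1.0 + spec.magnitude)
            if a_new <= 0:
                raise ValidationError(
                    f"DIF on {spec.item!r} yields non-positive discrimination"
                )
            new = replace(base, a=a_new, group=spec.group)
        # merge with any earlier effect on the same (item, group)
        recs = [r for r in recs if not (r.item_id == spec.item and r.group == spec.group)]
        recs.append(new)
    return ItemParameterSet(recs, D=params.D)


def _draw_group(rng, spec: GroupSpec):
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, spec.theta_age_corr], [spec.theta_age_corr, 1.0]],
        size=spec.n,
    )
    theta = spec.theta_mean + spec.theta_sd * z[:, 0]
    lo, hi = spec.age_range
    a_std = (lo - spec.age_mean) / spec.age_sd
    b_std = (hi - spec.age_mean) / spec.age_sd
    # Gaussian copula: age is truncated normal, rank-coupled to theta
    age = truncnorm.ppf(norm.cdf(z[:, 1]), a_std, b_std, loc=spec.age_mean, scale=spec.age_sd)
    return theta, age


def simulate_responses(
    params: ItemParameterSet, config: SimulationConfig
) -> tuple[ResponseMatrix, StudyFrame, pd.Series]:
    """Sample responses for every group; returns (responses, study, true thetas)."""
    rng = np.random.default_rng(config.seed + 1)
    frames = []
    resp_rows = []
    thetas = []
    ids = []
    for spec in config.groups:
        theta, age = _draw_group(rng, spec)
        pm = params.for_group(spec.label if params.groups else None)
        n = spec.n
        block = np.empty((n, len(params.item_ids)), dtype=float)
        for j, it in enumerate(params.item_ids):
            P = category_response_prob(pm[it], theta, params.D)  # (n, K)
            cum = np.cumsum(P, axis=1)
            u = rng.random(n)
            block[:, j] = (u[:, None] > cum).sum(axis=1)
        pid = [f"{spec.label}_{i + 1:05d}" for i in range(n)]
        ids.extend(pid)
        resp_rows.append(block)
        thetas.append(pd.Series(theta, index=pid))
        frames.append(pd.DataFrame({"group": spec.label, "age": age}, index=pid))
    values = pd.DataFrame(np.vstack(resp_rows), index=ids, columns=params.item_ids)
    ncat = {it: params.n_categories(it) for it in params.item_ids}
    responses = ResponseMatrix(values, ncat)
    study = StudyFrame(pd.concat(frames))
    return responses, study, pd.concat(thetas)


@dataclass
class StudyFixture:
    """A complete synthetic study: data plus its generating truth."""

    responses: ResponseMatrix
    study: StudyFrame
    true_theta: pd.Series
    params_reference: ItemParameterSet  # DIF-free generating bank
    params_true: ItemParameterSet  # bank with group-specific DIF records
    dif_items: tuple[str, ...]
    config: SimulationConfig


# Three-country study margins: sample sizes, latent means on the (T-50)/10
# metric, observed-score spreads, and age distributions per group.
FIXTURE_GROUPS = (
    GroupSpec("USA", 1600, theta_mean=0.027, theta_sd=1.226,
              age_mean=44.27, age_sd=16.15),
    GroupSpec("Germany", 1000, theta_mean=0.137, theta_sd=1.028,
              age_mean=44.93, age_sd=14.54),
    GroupSpec("Argentina", 1001, theta_mean=0.277, theta_sd=0.784,
              age_mean=35.58, age_sd=11.84),
)

# Four DIF items mirroring the flagged pattern: three uniform shifts (both
# directions, one large) plus one non-uniform slope change.  The slope
# doubling is the smallest change of this kind that the pseudo-R² and beta
# criteria detect at these sample sizes without saturating them; milder
# slope changes are invisible to everything but the raw likelihood-ratio
# test (see docs/methods.md).
FIXTURE_DIF = (
    DIFSpec("I06", "Germany", "uniform", +0.5),
    DIFSpec("I13", "Argentina", "uniform", -0.5),
    DIFSpec("I21", "Argentina", "uniform", +1.0),
    DIFSpec("I22", "Argentina", "nonuniform", 1.0),
)


def make_study_fixture(seed: int = 0, dif: tuple[DIFSpec, ...] = FIXTURE_DIF) -> StudyFixture:
    """The default synthetic three-country study (3601 persons, 35 items)."""
    config = SimulationConfig(
        n_items=35, n_categories=5, groups=FIXTURE_GROUPS, dif=tuple(dif), seed=seed
    )
    bank = simulate_item_bank(config)
    true_params = inject_dif(bank, config.dif)
    responses, study, theta = simulate_responses(true_params, config)
    return StudyFixture(
        responses=responses,
        study=study,
        true_theta=theta,
        params_reference=bank,
        params_true=true_params,
        dif_items=tuple(dict.fromkeys(d.item for d in config.dif)),
        config=config,
    )
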