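"""Enumerate and execute the factorial grid of DIF analytic choices.

The canonical grid crosses five factors — country comparison (all three or
one of the three pairs), age adjustment (yes/no), item-parameter source
(published calibration vs multigroup estimate from the data), flagging
criterion and threshold — giving 272 cells, 176 of them non-LRT.  Cells
that differ only in criterion/threshold share the same nested model fits,
so the whole grid costs one set of fits per (comparison, age, source)
base configuration; criteria are applied as a second pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ItemParameterSet, ResponseMatrix, StudyFrame, ValidationError
from .dif import CRITERIA, LRT_CRITERIA, DIFItemResult, dif_statistics_item, flag_items
from .grm import MultigroupGRM, eap_score

__all__ = [
    "AnalysisSpec",
    "GridConfig",
    "enumerate_grid",
    "MultiverseDIF",
    "MultiverseResults",
    "MultiverseSummary",
    "run_multiverse",
]


@dataclass(frozen=True)
class AnalysisSpec:
    """One cell of the multiverse."""

    cell_id: str
    comparison: tuple[str, ...]
    age_adjustment: bool
    parameter_source: str  # "estimated" | "published"
    criterion: str
    threshold: float

    def __post_init__(self):
        if len(self.comparison) < 2:
            raise ValidationError("comparison needs >= 2 groups")
        if self.parameter_source not in ("estimated", "published"):
            raise ValidationError(f"unknown parameter source {self.parameter_source!r}")
        if self.criterion not in CRITERIA:
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        if self.threshold not in CRITERIA[self.criterion]:
            raise ValidationError(
                f"threshold {self.threshold} not in the declared set for "
                f"{self.criterion}: {CRITERIA[self.criterion]}"
            )

    @property
    def base_key(self) -> tuple:
        return (self.comparison, self.age_adjustment, self.parameter_source)

    @property
    def is_lrt(self) -> bool:
        return self.criterion in LRT_CRITERIA


@dataclass(frozen=True)
class GridConfig:
    """Factor levels of the grid; the defaults reproduce the canonical 272."""

    groups: tuple[str, ...] = ("USA", "Germany", "Argentina")
    comparisons: tuple[tuple[str, ...], ...] | None = None
    age_adjustment: tuple[bool, ...] = (False, True)
    parameter_sources: tuple[str, ...] = ("estimated", "published")
    criteria: dict = field(default_factory=lambda: {k: tuple(v) for k, v in CRITERIA.items()})

    def resolved_comparisons(self) -> tuple[tuple[str, ...], ...]:
        if self.comparisons is not None:
            return tuple(tuple(c) for c in self.comparisons)
        pairs = tuple(itertools.combinations(self.groups, 2))
        # with two groups the all-groups comparison IS the single pair
        return tuple(dict.fromkeys((tuple(self.groups),) + pairs))

    @classmethod
    def from_dict(cls, d: dict) -> "GridConfig":
        kw: dict = {}
        if "groups" in d:
            kw["groups"] = tuple(d["groups"])
        if "comparisons" in d:
            kw["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        if "age_adjustment" in d:
            kw["age_adjustment"] = tuple(bool(x) for x in d["age_adjustment"])
        if "parameter_sources" in d:
            kw["parameter_sources"] = tuple(d["parameter_sources"])
        if "criteria" in d:
            kw["criteria"] = {k: tuple(v) for k, v in d["criteria"].items()}
        return cls(**kw)


def enumerate_grid(config: GridConfig | None = None) -> list[AnalysisSpec]:
    """All cells of the factorial grid, deterministically ordered."""
    config = config or GridConfig()
    cells: list[AnalysisSpec] = []
    seen: set[tuple] = set()
    i = 0
    for comp in config.resolved_comparisons():
        for age in config.age_adjustment:
            for src in config.parameter_sources:
                for crit, thresholds in config.criteria.items():
                    for thr in thresholds:
                        key = (comp, age, src, crit, thr)
                        if key in seen:
                            raise ValidationError(f"duplicate cell {key}")
                        seen.add(key)
                        i += 1
                        cid = (
                            f"c{i:03d}|{'-'.join(comp)}|age={int(age)}|{src}|"
                            f"{crit}@{thr:g}"
                        )
                        cells.append(AnalysisSpec(cid, comp, age, src, crit, thr))
    return cells


@dataclass
class MultiverseSummary:
    """Flag-frequency aggregation across the grid."""

    per_cell_flag_count: pd.Series  # cell_id -> number of flagged items
    histogram: pd.Series  # n flagged -> number of cells
    per_item: pd.DataFrame  # k_all, pct_all, k_nonlrt, pct_nonlrt per item
    factor_breakdowns: pd.DataFrame  # factor, level, flags, pct_nonlrt, pct_all
    n_cells: int
    n_cells_nonlrt: int
    n_items: int

    def consistent_items(self, cutoff: float = 0.10, basis: str = "non_lrt") -> set[str]:
        """Items flagged in strictly more than ``cutoff`` of analyses."""
        col = "pct_nonlrt" if basis == "non_lrt" else "pct_all"
        frac = self.per_item[col] / 100.0
        return set(self.per_item.index[frac > cutoff])


class MultiverseDIF:
    """The multiverse DIF model: data in, 272 analyses out.

    Parameters
    ----------
    responses, study : the item responses and covariates
    published_params : ItemParameterSet, optional
        Fixed calibration for the "published" parameter-source factor;
        required iff the grid contains such cells.
    reference_group : str
        Group whose latent distribution anchors the metric (default: first
        group of the grid config present in the data).
    """

    def __init__(
        self,
        responses: ResponseMatrix,
        study: StudyFrame,
        grid: GridConfig | None = None,
        published_params: ItemParameterSet | None = None,
        reference_group: str | None = None,
        D: float = 1.0,
    ):
        self.responses, self.study = study.align(responses)
        self.grid_config = grid or GridConfig(groups=tuple(self.study.groups))
        self.cells = enumerate_grid(self.grid_config)
        if any(c.parameter_source == "published" for c in self.cells) and published_params is None:
            raise ValidationError(
                "grid contains 'published' parameter-source cells but no "
                "published_params were supplied"
            )
        self.published_params = published_params
        self.reference_group = reference_group or self.grid_config.groups[0]
        self.D = D

    # -- shared machinery ---------------------------------------------------

    def _subset(self, comparison):
        study = self.study.subset(comparison)
        resp = self.responses.subset_persons(study.persons)
        return resp, study

    def _thetas(self, comparison, source, _grm_cache):
        resp, study = self._subset(comparison)
        if source == "published":
            scores = eap_score(resp, self.published_params)
        else:
            if comparison not in _grm_cache:
                _grm_cache[comparison] = MultigroupGRM(
                    resp, study, reference_group=self._ref_for(comparison), D=self.D
                ).fit()
            scores = _grm_cache[comparison].score(resp, study=study)
        return resp, study, scores["theta"]

    def _ref_for(self, comparison):
        return (
            self.reference_group
            if self.reference_group in comparison
            else comparison[0]
        )

    def _base_stats(self, comparison, age_adj, source, _grm_cache) -> list[DIFItemResult]:
        resp, study, theta = self._thetas(comparison, source, _grm_cache)
        g = study.group_of().to_numpy()
        age = study.frame["age"].to_numpy()
        out = []
        for item in resp.items:
            out.append(
                dif_statistics_item(
                    resp.values[item].to_numpy(),
                    theta.to_numpy(),
                    g,
                    age=age,
                    adjust_age=age_adj,
                    item_id=item,
                    reference_group=self._ref_for(comparison),
                )
            )
        return out

    # -- fitting ------------------------------------------------------------

    def fit(self, shared_fits: bool = True) -> "MultiverseResults":
        """Execute every cell.

        ``shared_fits=False`` recomputes the model fits independently for
        every cell (a correctness oracle for the cached path; identical
        output, much slower).
        """
        grm_cache: dict = {}
        base_stats: dict[tuple, list[DIFItemResult]] = {}
        flags: dict[str, set[str]] = {}
        for cell in self.cells:
            if shared_fits:
                if cell.base_key not in base_stats:
                    base_stats[cell.base_key] = self._base_stats(
                        *cell.base_key, grm_cache
                    )
                stats = base_stats[cell.base_key]
            else:
                stats = self._base_stats(*cell.base_key, {})
                base_stats.setdefault(cell.base_key, stats)
            flags[cell.cell_id] = flag_items(stats, cell.criterion, cell.threshold)
        return MultiverseResults(
            cells=self.cells,
            base_stats=base_stats,
            flags=flags,
            item_ids=self.responses.items,
        )


@dataclass
class MultiverseResults:
    """Per-cell DIF statistics and flags for a fitted multiverse."""

    cells: list[AnalysisSpec]
    base_stats: dict[tuple, list[DIFItemResult]]
    flags: dict[str, set[str]]
    item_ids: list[str]

    def stats_frame(self) -> pd.DataFrame:
        """Tidy statistics: one row per (base configuration, item)."""
        rows = []
        for (comp, age, src), stats in self.base_stats.items():
            for r in stats:
                row = {
                    "comparison": "-".join(comp),
                    "age_adjustment": age,
                    "parameter_source": src,
                }
                row.update(r.as_row())
                rows.append(row)
        return pd.DataFrame(rows)

    def flags_frame(self) -> pd.DataFrame:
        """One row per (cell, item) with a boolean flag."""
        rows = []
        for cell in self.cells:
            fl = self.flags[cell.cell_id]
            for item in self.item_ids:
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "comparison": "-".join(cell.comparison),
                        "age_adjustment": cell.age_adjustment,
                        "parameter_source": cell.parameter_source,
                        "criterion": cell.criterion,
                        "threshold": cell.threshold,
                        "flagged": item in fl,
                        "item_id": item,
                    }
                )
        return pd.DataFrame(rows)

    def aggregate(self) -> MultiverseSummary:
        """Flag-frequency summaries: histogram, per-item and per-factor tables."""
        n_items = len(self.item_ids)
        nonlrt = [c for c in self.cells if not c.is_lrt]
        n_cells, n_nonlrt = len(self.cells), len(nonlrt)
        counts = pd.Series(
            {c.cell_id: len(self.flags[c.cell_id]) for c in self.cells}, name="n_flagged"
        )
        hist = counts.value_counts().sort_index()
        hist.index.name = "n_flagged"

        k_all = {i: 0 for i in self.item_ids}
        k_non = {i: 0 for i in self.item_ids}
        for c in self.cells:
            for i in self.flags[c.cell_id]:
                k_all[i] += 1
                if not c.is_lrt:
                    k_non[i] += 1
        per_item = pd.DataFrame(
            {
                "k_all": pd.Series(k_all),
                "k_nonlrt": pd.Series(k_non),
            }
        ).loc[self.item_ids]
        per_item["pct_all"] = 100.0 * per_item["k_all"] / n_cells
        per_item["pct_nonlrt"] = (
            100.0 * per_item["k_nonlrt"] / n_nonlrt if n_nonlrt else np.nan
        )
        per_item.index.name = "item_id"

        def _level(cell: AnalysisSpec, factor: str):
            if factor == "comparison":
                return "-".join(cell.comparison)
            if factor == "age_adjustment":
                return "adjusted" if cell.age_adjustment else "unadjusted"
            if factor == "parameter_source":
                return cell.parameter_source
            return cell.criterion

        rows = []
        for factor in ("comparison", "age_adjustment", "parameter_source", "criterion"):
            levels: dict[str, dict[str, int]] = {}
            for c in self.cells:
                lv = _level(c, factor)
                d = levels.setdefault(lv, {"flags_all": 0, "flags_nonlrt": 0})
                nf = len(self.flags[c.cell_id])
                d["flags_all"] += nf
                if not c.is_lrt:
                    d["flags_nonlrt"] += nf
            for lv, d in levels.items():
                rows.append(
                    {
                        "factor": factor,
                        "level": lv,
                        "flags": d["flags_all"],
                        "pct_nonlrt": 100.0 * d["flags_nonlrt"] / (n_nonlrt * n_items)
                        if n_nonlrt
                        else np.nan,
                        "pct_all": 100.0 * d["flags_all"] / (n_cells * n_items),
                    }
                )
        breakdowns = pd.DataFrame(rows)
        return MultiverseSummary(
            per_cell_flag_count=counts,
            histogram=hist,
            per_item=per_item,
            factor_breakdowns=breakdowns,
            n_cells=n_cells,
            n_cells_nonlrt=n_nonlrt,
            n_items=n_items,
        )

    def consistent_items(self, cutoff: float = 0.10, basis: str = "non_lrt") -> set[str]:
        return self.aggregate().consistent_items(cutoff=cutoff, basis=basis)

    def summary(self) -> str:
        agg = self.aggregate()
        top = agg.per_item.sort_values("pct_nonlrt", ascending=False).head(6)
        lines = [
            f"Multiverse DIF analysis: {agg.n_cells} cells "
            f"({agg.n_cells_nonlrt} non-LRT), {agg.n_items} items",
            f"consistent DIF items (>10% of non-LRT analyses): "
            f"{sorted(agg.consistent_items())}",
            "most-flagged items (non-LRT basis):",
            top[["k_nonlrt", "pct_nonlrt", "k_all", "pct_all"]].to_string(),
        ]
        return "\n".join(lines)


def run_multiverse(
    responses: ResponseMatrix,
    study: StudyFrame,
    grid: GridConfig | None = None,
    published_params: ItemParameterSet | None = None,
    shared_fits: bool = True,
    **kw,
) -> MultiverseResults:
    """Functional wrapper: build and fit a :class:`MultiverseDIF`."""
    return MultiverseDIF(
        responses, study, grid=grid, published_params=published_params, **kw
    ).fit(shared_fits=shared_fits)
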