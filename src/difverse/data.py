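"""Core data containers: item parameters, response matrices, study covariates.

All containers are thin, validated wrappers around pandas/numpy objects so
that every downstream routine can rely on ordered thresholds, positive
discriminations and consistent person/item bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "ItemParameterSet",
    "ResponseMatrix",
    "StudyFrame",
    "GroupDistribution",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class ItemParameters:
    """Graded-response parameters of one item, on the logit metric.

    ``a`` is the discrimination (slope), ``b`` the strictly increasing
    category thresholds b_1 < ... < b_{K-1}.  ``group`` is ``None`` for a
    record shared across groups, or a group label for a group-specific
    (partial-invariance) record.
    """

    item_id: str
    a: float
    b: tuple[float, ...]
    group: str | None = None

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a", float(self.a))
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValidationError(
                f"item {self.item_id!r}: discrimination must be > 0, got {self.a}"
            )
        if len(b) < 1:
            raise ValidationError(f"item {self.item_id!r}: needs >= 1 threshold")
        arr = np.asarray(b, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"item {self.item_id!r}: non-finite threshold")
        if np.any(np.diff(arr) <= 0):
            raise ValidationError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, got {b}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


class ItemParameterSet:
    """A calibration: one or more :class:`ItemParameters` per item.

    An item may carry one shared record (``group=None``) and/or
    group-specific records.  ``for_group(g)`` resolves the applicable record
    per item, preferring the group-specific one.  ``D`` is the scaling
    constant of the logistic (1.0 = pure logistic metric; 1.702 files are
    converted on read, see :func:`difverse.io.read_item_parameters`).
    """

    def __init__(self, records: Iterable[ItemParameters], D: float = 1.0):
        records = list(records)
        if not records:
            raise ValidationError("empty parameter set")
        seen: set[tuple[str, str | None]] = set()
        for r in records:
            key = (r.item_id, r.group)
            if key in seen:
                raise ValidationError(f"duplicate parameter record for {key}")
            seen.add(key)
        self._records = records
        self.D = float(D)
        # preserve first-appearance item order
        self.item_ids: list[str] = list(dict.fromkeys(r.item_id for r in records))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> list[ItemParameters]:
        return list(self._records)

    @property
    def groups(self) -> list[str]:
        return sorted({r.group for r in self._records if r.group is not None})

    def n_categories(self, item_id: str) -> int:
        for r in self._records:
            if r.item_id == item_id:
                return r.n_categories
        raise KeyError(item_id)

    def for_group(self, group: str | None = None) -> dict[str, ItemParameters]:
        """Resolve one record per item for ``group`` (specific beats shared)."""
        out: dict[str, ItemParameters] = {}
        for r in self._records:
            if r.group is None and r.item_id not in out:
                out[r.item_id] = r
        if group is not None:
            for r in self._records:
                if r.group == group:
                    out[r.item_id] = r
        missing = [i for i in self.item_ids if i not in out]
        if missing:
            raise ValidationError(
                f"no applicable parameter record for items {missing} in group {group!r}"
            )
        return out

    def subset(self, item_ids: Sequence[str]) -> "ItemParameterSet":
        keep = set(item_ids)
        recs = [r for r in self._records if r.item_id in keep]
        return ItemParameterSet(recs, D=self.D)

    def with_metric(self, D: float) -> "ItemParameterSet":
        """Re-express the same response model under scaling constant ``D``.

        Probabilities are invariant: a_new = a_old * D_old / D_new.
        """
        scale = self.D / float(D)
        recs = [replace(r, a=r.a * scale) for r in self._records]
        return ItemParameterSet(recs, D=float(D))

    def to_frame(self) -> pd.DataFrame:
        kmax = max(r.n_categories for r in self._records)
        rows = []
        for r in self._records:
            row: dict[str, object] = {
                "item_id": r.item_id,
                "group": "" if r.group is None else r.group,
                "a": r.a,
            }
            for j in range(kmax - 1):
                row[f"b{j + 1}"] = r.b[j] if j < len(r.b) else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, D: float = 1.0) -> "ItemParameterSet":
        bcols = sorted(
            (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        recs = []
        for _, row in df.iterrows():
            group = row.get("group", "")
            group = None if (pd.isna(group) or str(group) == "") else str(group)
            b = [row[c] for c in bcols if pd.notna(row[c])]
            recs.append(ItemParameters(str(row["item_id"]), float(row["a"]), tuple(b), group))
        return cls(recs, D=D)


@dataclass(frozen=True)
class GroupDistribution:
    """Latent-trait distribution of one group on the reference metric."""

    group: str
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd <= 0:
            raise ValidationError(f"group {self.group!r}: invalid (mean, sd)")


class ResponseMatrix:
    """Persons x items ordinal responses, 0-based categories, NaN = missing."""

    def __init__(self, values: pd.DataFrame, n_categories: Mapping[str, int] | None = None):
        df = values.astype(float)
        if df.index.has_duplicates:
            raise ValidationError("duplicate person ids")
        obs = df.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = np.nansum(np.abs(obs - np.round(obs))) > 0
        if bad or np.nanmin(obs, initial=0) < 0:
            raise ValidationError("responses must be non-negative integer categories")
        if n_categories is None:
            n_categories = {
                c: int(np.nanmax(df[c].to_numpy())) + 1 if df[c].notna().any() else 2
                for c in df.columns
            }
        for c in df.columns:
            k = int(n_categories[c])
            if k < 2:
                raise ValidationError(f"item {c!r}: needs >= 2 categories")
            col = df[c].dropna()
            if len(col) and col.max() > k - 1:
                p = col.idxmax()
                raise ValidationError(
                    f"item {c!r}, person {p!r}: category {int(col.max())} outside 0..{k - 1}"
                )
        self.values = df
        self.n_categories = {c: int(n_categories[c]) for c in df.columns}

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)

    @property
    def persons(self) -> list:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.values[list(item_ids)], self.n_categories)

    def subset_persons(self, persons: Sequence) -> "ResponseMatrix":
        return ResponseMatrix(self.values.loc[list(persons)], self.n_categories)


class StudyFrame:
    """One row per person: group membership and (optional) age in years."""

    def __init__(self, frame: pd.DataFrame):
        if "group" not in frame.columns:
            raise ValidationError("study frame needs a 'group' column")
        if frame.index.has_duplicates:
            raise ValidationError("duplicate person ids in study frame")
        df = frame.copy()
        df["group"] = df["group"].astype(str)
        if "age" not in df.columns:
            df["age"] = np.nan
        self.frame = df

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    @property
    def persons(self) -> list:
        return list(self.frame.index)

    def group_of(self) -> pd.Series:
        return self.frame["group"]

    def subset(self, groups: Sequence[str]) -> "StudyFrame":
        keep = self.frame[self.frame["group"].isin(list(groups))]
        present = set(keep["group"])
        empty = [g for g in groups if g not in present]
        if empty:
            raise ValidationError(f"empty group(s) in subset: {empty}")
        return StudyFrame(keep)

    def align(self, responses: ResponseMatrix) -> tuple[ResponseMatrix, "StudyFrame"]:
        common = [p for p in responses.persons if p in set(self.frame.index)]
        if not common:
            raise ValidationError("no persons shared between responses and study frame")
        return responses.subset_persons(common), StudyFrame(self.frame.loc[common])
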