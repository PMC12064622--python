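"""Readers and writers for the tool's plain-text formats.

Response files are wide CSV (person_id, group, age, then one integer column
per item; empty cells = missing).  Item-parameter files are CSV with a
``# metric_constant: <D>`` header line (or JSON with a ``metric_constant``
field); parameters declared on the normal-ogive 1.702 metric are converted
to the internal pure-logistic metric on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ItemParameters,
    ItemParameterSet,
    ResponseMatrix,
    StudyFrame,
    ValidationError,
)

__all__ = [
    "read_responses",
    "write_responses",
    "read_item_parameters",
    "write_item_parameters",
]

INTERNAL_D = 1.0
_META_COLS = ("person_id", "group", "age")


def read_responses(
    path, one_based: bool = False, n_categories: dict | None = None
) -> tuple[ResponseMatrix, StudyFrame]:
    """Load a wide response CSV into (ResponseMatrix, StudyFrame).

    ``one_based=True`` recodes category files coded 1..K to the internal
    0..K-1 convention.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("person_id", "group") if c not in df.columns]
    if missing:
        raise ValidationError(f"response file lacks column(s) {missing}")
    df = df.set_index("person_id")
    items = [c for c in df.columns if c not in _META_COLS]
    if not items:
        raise ValidationError("response file has no item columns")
    resp = df[items].astype(float)
    for c in items:
        col = resp[c].dropna()
        if len(col) and np.any(col != np.round(col)):
            p = col.index[col != np.round(col)][0]
            raise ValidationError(
                f"non-integer category in item {c!r}, person {p!r}"
            )
    if one_based:
        resp = resp - 1.0
        if (resp < 0).any().any():
            raise ValidationError("category 0 found in a file declared 1-based")
    study = StudyFrame(df[[c for c in ("group", "age") if c in df.columns]])
    return ResponseMatrix(resp, n_categories), study


def write_responses(path, responses: ResponseMatrix, study: StudyFrame) -> None:
    resp, study = study.align(responses)
    out = pd.concat([study.frame[["group", "age"]], resp.values], axis=1)
    out.index.name = "person_id"
    # integer-format categories, keep missing as empty cells
    for c in resp.items:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path)


def read_item_parameters(path) -> ItemParameterSet:
    """Load an item-parameter file (CSV with metric header, or JSON).

    Files on another metric constant (e.g. 1.702) are converted so that the
    response probabilities are unchanged on the internal D = 1 metric.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        D = float(payload.get("metric_constant", INTERNAL_D))
        recs = [
            ItemParameters(
                str(r["item_id"]),
                float(r["a"]),
                tuple(float(x) for x in r["b"]),
                r.get("group") or None,
            )
            for r in payload["items"]
        ]
        params = ItemParameterSet(recs, D=D)
    else:
        D = INTERNAL_D
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "metric_constant" not in first:
                    raise ValidationError(
                        "parameter file header must declare metric_constant"
                    )
                D = float(first.split(":", 1)[1])
                df = pd.read_csv(fh)
            else:
                raise ValidationError(
                    "parameter CSV must start with a '# metric_constant: <D>' header"
                )
        params = ItemParameterSet.from_frame(df, D=D)
    if params.D != INTERNAL_D:
        params = params.with_metric(INTERNAL_D)
    return params


def write_item_parameters(path, params: ItemParameterSet) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "metric_constant": params.D,
            "items": [
                {"item_id": r.item_id, "group": r.group, "a": r.a, "b": list(r.b)}
                for r in params
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        with open(path, "w") as fh:
            fh.write(f"# metric_constant: {params.D}\n")
            params.to_frame().to_csv(fh, index=False)
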