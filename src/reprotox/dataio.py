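"""Reading, writing and joining descriptor tables, label tables and reports.

Descriptor tables are delimited text: first column the chemical ID, header
row of descriptor names, numeric cells.  Label tables carry the binary
reproductive-toxicity call (``positive``/``negative``) and, for positives,
the LOAEL dose in mg/kg/day.  The dialect (comma vs tab) is auto-detected
from the file extension and can be overridden.  Missing values are
disallowed unless a missing-value token is configured explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "LabelTable",
    "LabeledDataset",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_label_table",
    "write_label_table",
    "join_dataset",
    "write_predictions",
    "write_metrics_report",
]

_TAB_SUFFIXES = {".tsv", ".tab", ".txt"}

POSITIVE, NEGATIVE = "positive", "negative"


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if Path(path).suffix.lower() in _TAB_SUFFIXES else ","


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(frozen=True)
class DescriptorTable:
    """Chemicals x named numeric descriptors — the universal feature carrier.

    Parameters
    ----------
    ids
        Ordered, unique chemical identifiers (rows).
    descriptor_names
        Ordered, unique descriptor names (columns).
    values
        Numeric matrix of shape ``(len(ids), len(descriptor_names))``.
    """

    ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(
            self, "descriptor_names", tuple(str(n) for n in self.descriptor_names)
        )
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.ids, "chemical IDs")
        _check_unique(self.descriptor_names, "descriptor names")
        if vals.shape != (len(self.ids), len(self.descriptor_names)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.ids)} ids x {len(self.descriptor_names)} descriptors"
            )

    @property
    def n_chemicals(self) -> int:
        return len(self.ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.ids), columns=list(self.descriptor_names)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DescriptorTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(float))

    def select_descriptors(self, names: Iterable[str]) -> "DescriptorTable":
        names = list(names)
        index = {n: j for j, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        cols = [index[n] for n in names]
        return DescriptorTable(self.ids, tuple(names), self.values[:, cols])

    def take(self, row_indices: Sequence[int]) -> "DescriptorTable":
        idx = np.asarray(row_indices, dtype=int)
        return DescriptorTable(
            tuple(self.ids[i] for i in idx), self.descriptor_names, self.values[idx]
        )


@dataclass(frozen=True)
class LabelTable:
    """Per-chemical binary toxicity label and optional LOAEL (mg/kg/day)."""

    ids: tuple[str, ...]
    labels: np.ndarray  # int {0, 1}; 1 = positive
    loael: np.ndarray  # float; NaN when absent

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        y = np.asarray(self.labels, dtype=int)
        lo = np.asarray(self.loael, dtype=float)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "loael", lo)
        _check_unique(self.ids, "chemical IDs")
        n = len(self.ids)
        if y.shape != (n,) or lo.shape != (n,):
            raise ValueError("labels/loael must be 1-D and aligned with ids")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be 0 (negative) or 1 (positive)")
        present = ~np.isnan(lo)
        if present.any() and not (lo[present] > 0).all():
            raise ValueError("LOAEL values must be strictly positive when present")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "label": [POSITIVE if v else NEGATIVE for v in self.labels],
                "loael": self.loael,
            }
        )


@dataclass(frozen=True)
class LabeledDataset:
    """Descriptor table joined with aligned labels and optional LOAELs."""

    table: DescriptorTable
    y: np.ndarray  # int {0,1} aligned with table.ids
    loael: np.ndarray  # float, NaN when absent

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        lo = np.asarray(self.loael, dtype=float)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "loael", lo)
        n = self.table.n_chemicals
        if y.shape != (n,) or lo.shape != (n,):
            raise ValueError("labels/loael not aligned with descriptor table")

    @property
    def ids(self) -> tuple[str, ...]:
        return self.table.ids

    @property
    def n_chemicals(self) -> int:
        return self.table.n_chemicals

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())

    def label_table(self) -> LabelTable:
        return LabelTable(self.table.ids, self.y, self.loael)

    def select_descriptors(self, names: Iterable[str]) -> "LabeledDataset":
        return LabeledDataset(self.table.select_descriptors(names), self.y, self.loael)

    def take(self, row_indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(row_indices, dtype=int)
        return LabeledDataset(self.table.take(idx), self.y[idx], self.loael[idx])


def read_descriptor_table(
    path: str | Path, sep: str | None = None, na_token: str | None = None
) -> DescriptorTable:
    """Parse a delimited descriptor table (first column ID, header row names).

    Non-numeric cells raise unless `na_token` is configured, in which case
    cells equal to the token become NaN (downstream stages reject NaN).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty descriptor file: {path}")
    df = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        index_col=0,
        na_values=[na_token] if na_token is not None else [],
        keep_default_na=False,
    )
    if df.shape[1] == 0:
        raise ValueError(f"no descriptor columns in {path}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in descriptor {col!r} of {path}") from exc
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate chemical IDs in {path}: {dup}")
    if na_token is None and df.isna().any().any():
        cols = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in descriptors {cols} (no missing-value token configured)")
    return DescriptorTable.from_dataframe(df)


def write_descriptor_table(table: DescriptorTable, path: str | Path, sep: str | None = None) -> None:
    table.to_dataframe().to_csv(Path(path), sep=_sep_for(path, sep), index_label="id")


def read_label_table(path: str | Path, sep: str | None = None) -> LabelTable:
    """Parse a label table with columns ``id``, ``label`` and optional ``loael``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={"id": str})
    required = {"id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table {path} must have columns {sorted(required)}")
    lab = df["label"].astype(str).str.strip().str.lower()
    known = {POSITIVE: 1, NEGATIVE: 0, "1": 1, "0": 0}
    unknown = sorted(set(lab) - set(known))
    if unknown:
        raise ValueError(f"unrecognized labels in {path}: {unknown}")
    y = lab.map(known).to_numpy(int)
    loael = (
        pd.to_numeric(df["loael"], errors="coerce").to_numpy(float)
        if "loael" in df.columns
        else np.full(len(df), np.nan)
    )
    return LabelTable(tuple(df["id"]), y, loael)


def write_label_table(labels: LabelTable, path: str | Path, sep: str | None = None) -> None:
    labels.to_dataframe().to_csv(Path(path), sep=_sep_for(path, sep), index=False)


def join_dataset(table: DescriptorTable, labels: LabelTable, strict: bool = True) -> LabeledDataset:
    """Align labels to the descriptor table by ID; row order follows the table.

    In strict mode every table ID must be labeled and every label must be
    used; violations are reported by ID.
    """
    pos = {i: k for k, i in enumerate(labels.ids)}
    missing = [i for i in table.ids if i not in pos]
    if missing:
        raise ValueError(f"IDs without labels: {missing}")
    if strict:
        surplus = sorted(set(labels.ids) - set(table.ids))
        if surplus:
            raise ValueError(f"labels for IDs absent from descriptor table: {surplus}")
    order = [pos[i] for i in table.ids]
    return LabeledDataset(table, labels.labels[order], labels.loael[order])


def write_predictions(records: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a prediction table (ID, label, probability, confidence, votes...).

    An empty frame still produces a header-only file.
    """
    records.to_csv(Path(path), sep=_sep_for(path, sep), index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def write_metrics_report(payload: dict, path: str | Path) -> None:
    """Serialize a metrics payload (aggregates + per-iteration values) as JSON."""
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")
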