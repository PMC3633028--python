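"""Attribute schemas and the typed cohort container.

A cohort is a table of patients described by a small number of declared
risk factors.  Each attribute is either *nominal* (a finite unordered set
of admissible values, e.g. tumour stage ``{1, 2, 3, 4, 4s}``) or *ordered*
(a numeric value inside a known finite interval, e.g. age at diagnosis).
Every patient carries a categorical outcome label; the label ``NC``
("not classified") is reserved for the classifier output and may not be
used as an outcome class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved output label for patterns covered by no rule.
NC = "NC"


class SchemaError(ValueError):
    """A value or attribute does not conform to the declared schema."""


@dataclass(frozen=True)
class AttributeSchema:
    """Declaration of one input attribute.

    Parameters
    ----------
    name:
        Column name; unique within a schema.
    kind:
        ``"nominal"`` or ``"ordered"``.
    values:
        Admissible values, for nominal attributes.
    low, high:
        Finite interval bounds, for ordered attributes.
    """

    name: str
    kind: str
    values: tuple[str, ...] = ()
    low: float = float("nan")
    high: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "ordered"):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "nominal":
            if not self.values:
                raise SchemaError(f"nominal attribute {self.name!r} has an empty domain")
            if len(set(self.values)) != len(self.values):
                raise SchemaError(f"duplicate values in domain of {self.name!r}")
        else:
            if not (np.isfinite(self.low) and np.isfinite(self.high)):
                raise SchemaError(f"ordered attribute {self.name!r} needs finite bounds")
            if not self.low < self.high:
                raise SchemaError(f"ordered attribute {self.name!r}: low must be < high")

    def contains(self, value) -> bool:
        if self.kind == "nominal":
            return value in self.values
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        return self.low <= v <= self.high


def nominal(name: str, values: Iterable[str]) -> AttributeSchema:
    return AttributeSchema(name, "nominal", values=tuple(values))


def ordered(name: str, low: float, high: float) -> AttributeSchema:
    return AttributeSchema(name, "ordered", low=float(low), high=float(high))


@dataclass
class CohortDataset:
    """A typed patient table with outcome labels.

    Attributes are stored column-wise in ``frame`` (indexed by unique
    instance ids) and validated against ``schema`` at construction.
    """

    schema: list[AttributeSchema]
    frame: pd.DataFrame
    outcome: pd.Series
    provenance: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        names = [a.name for a in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("attribute names must be unique")
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise SchemaError(f"columns missing from data: {missing}")
        self.frame = self.frame.loc[:, names].copy()
        if not self.frame.index.is_unique:
            raise SchemaError("instance ids must be unique")
        self.outcome = self.outcome.reindex(self.frame.index)
        if self.outcome.isna().any():
            raise SchemaError("every instance needs an outcome label")
        if (self.outcome.astype(str) == NC).any():
            raise SchemaError(f"{NC!r} is reserved and may not be an outcome label")
        for attr in self.schema:
            col = self.frame[attr.name]
            if col.isna().any():
                row = col.index[col.isna()][0]
                raise SchemaError(f"missing value at row {row!r}, column {attr.name!r}")
            if attr.kind == "ordered":
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any():
                    row = col.index[vals.isna()][0]
                    raise SchemaError(
                        f"non-numeric value {col[row]!r} at row {row!r}, "
                        f"column {attr.name!r}"
                    )
                bad = ~((vals >= attr.low) & (vals <= attr.high))
                if bad.any():
                    row = col.index[bad][0]
                    raise SchemaError(
                        f"value {col[row]!r} at row {row!r} outside bounds "
                        f"[{attr.low}, {attr.high}] of column {attr.name!r}"
                    )
                self.frame[attr.name] = vals.astype(float)
            else:
                col = col.astype(str)
                bad = ~col.isin(attr.values)
                if bad.any():
                    row = col.index[bad][0]
                    raise SchemaError(
                        f"value {col[row]!r} at row {row!r} outside domain "
                        f"of column {attr.name!r}"
                    )
                self.frame[attr.name] = col

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Index:
        return self.frame.index

    @property
    def classes(self) -> list[str]:
        return sorted(self.outcome.astype(str).unique())

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.schema]

    def attribute(self, name: str) -> AttributeSchema:
        for a in self.schema:
            if a.name == name:
                return a
        raise SchemaError(f"unknown attribute {name!r}")

    def subset(self, ids: Sequence) -> "CohortDataset":
        prov = self.provenance.loc[ids] if self.provenance is not None else None
        return CohortDataset(self.schema, self.frame.loc[ids],
                             self.outcome.loc[ids], prov)

    def drop(self, ids: Iterable) -> "CohortDataset":
        keep = self.frame.index.difference(pd.Index(ids), sort=False)
        return self.subset(keep)

    def profiles(self) -> pd.Series:
        """Full attribute profile of each instance, as a tuple."""
        return pd.Series(
            list(map(tuple, self.frame.itertuples(index=False, name=None))),
            index=self.frame.index,
        )


def make_dataset(
    schema: Sequence[AttributeSchema],
    rows: Sequence[Mapping],
    outcome: str = "outcome",
    ids: Sequence | None = None,
) -> CohortDataset:
    """Convenience constructor from a list of row dicts (used by tests)."""
    frame = pd.DataFrame(list(rows))
    if ids is not None:
        frame.index = pd.Index(ids)
    y = frame.pop(outcome)
    return CohortDataset(list(schema), frame, y)
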