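"""Tabular discrete observations with missing-value support.

A :class:`DataTable` wraps a pandas DataFrame whose columns are
categoricals with the declared state order; missing cells are ``NaN``
(integer code ``-1``).  All counting in the learners goes through the
integer code matrix, so the declared state order is authoritative
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .network import DiscreteVariable


@dataclass
class ExclusionReport:
    retained: int
    excluded: int


class DataTable:
    def __init__(self, variables: Sequence[DiscreteVariable], df: pd.DataFrame):
        self.variables: list[DiscreteVariable] = list(variables)
        self._by_name = {v.name: v for v in self.variables}
        if list(df.columns) != [v.name for v in self.variables]:
            raise ValidationError("DataFrame columns do not match declared variables")
        self.df = df

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_codes(
        cls, variables: Sequence[DiscreteVariable], codes: Mapping[str, np.ndarray]
    ) -> "DataTable":
        cols = {}
        for v in variables:
            cols[v.name] = pd.Categorical.from_codes(
                np.asarray(codes[v.name], dtype=np.int64), categories=list(v.states)
            )
        return cls(variables, pd.DataFrame(cols))

    @classmethod
    def from_records(
        cls,
        variables: Sequence[DiscreteVariable],
        records: Iterable[Mapping[str, str | None]],
    ) -> "DataTable":
        names = [v.name for v in variables]
        raw = pd.DataFrame(list(records), columns=names)
        return cls.from_strings(variables, raw)

    @classmethod
    def from_strings(
        cls, variables: Sequence[DiscreteVariable], raw: pd.DataFrame
    ) -> "DataTable":
        """Validate string cells against declared states; None/NaN/"" = missing."""
        cols = {}
        for v in variables:
            col = raw[v.name].astype(object)
            col = col.where(~pd.isna(col), None)
            col = col.map(lambda x: None if x == "" else x)
            bad = col[~col.isin(list(v.states) + [None])]
            if len(bad):
                row = bad.index[0]
                raise ValidationError(
                    f"undeclared state {bad.iloc[0]!r} for variable {v.name!r} "
                    f"at row {row}"
                )
            cols[v.name] = pd.Categorical(col, categories=list(v.states))
        return cls(variables, pd.DataFrame(cols))

    # -- basics -------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def variable(self, name: str) -> DiscreteVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise DomainError(f"unknown variable {name!r}") from None

    def codes(self, name: str) -> np.ndarray:
        """Integer codes for a column; -1 marks missing."""
        self.variable(name)
        return self.df[name].cat.codes.to_numpy()

    def code_matrix(self, names: Sequence[str]) -> np.ndarray:
        return np.stack([self.codes(n) for n in names], axis=1)

    def complete_mask(self, names: Sequence[str]) -> np.ndarray:
        m = np.ones(self.n_rows, dtype=bool)
        for n in names:
            m &= self.codes(n) >= 0
        return m

    def missing_fraction_per_row(self) -> np.ndarray:
        miss = np.stack(
            [self.codes(v.name) < 0 for v in self.variables], axis=1
        )
        return miss.mean(axis=1)

    def subset_rows(self, index: np.ndarray) -> "DataTable":
        return DataTable(self.variables, self.df.iloc[index].reset_index(drop=True))

    def subset_columns(self, names: Sequence[str]) -> "DataTable":
        vs = [self.variable(n) for n in names]
        return DataTable(vs, self.df[list(names)].copy())

    def record(self, i: int) -> dict[str, str]:
        """Row ``i`` as a partial assignment (missing cells omitted)."""
        out = {}
        for v in self.variables:
            code = self.df[v.name].cat.codes.iloc[i]
            if code >= 0:
                out[v.name] = v.states[code]
        return out

    def to_csv(self, path) -> None:
        out = self.df.astype(object).where(~self.df.isna(), "")
        out.to_csv(path, index=False)

    def __eq__(self, other) -> bool:  # used by determinism tests
        return (
            isinstance(other, DataTable)
            and self.variables == other.variables
            and self.df.equals(other.df)
        )


def exclude_incomplete(
    data: DataTable, max_missing_fraction: float = 0.2
) -> tuple[DataTable, ExclusionReport]:
    """Drop records whose missing-column fraction exceeds the threshold.

    Mirrors the survey-cleaning step in which subjects with too many
    unanswered items are removed before modelling.
    """
    frac = data.missing_fraction_per_row()
    keep = frac <= max_missing_fraction
    report = ExclusionReport(retained=int(keep.sum()), excluded=int((~keep).sum()))
    return data.subset_rows(np.flatnonzero(keep)), report
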