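"""Subject-level feature tables.

A :class:`FeatureTable` is a thin wrapper around a pandas DataFrame with the
metadata columns ``subject_id``, ``group``, ``sex``, ``age`` followed by one
column per registry parameter.  It round-trips through CSV with the
parameter abbreviations as the header row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import pandas as pd

__all__ = ["FeatureTable", "META_COLUMNS"]

META_COLUMNS = ["subject_id", "group", "sex", "age"]


@dataclass
class FeatureTable:
    """Subjects x parameters matrix with group/sex/age labels."""

    data: pd.DataFrame
    parameters: List[str]

    def __post_init__(self):
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing metadata columns "
                             f"{missing}")
        missing = [p for p in self.parameters if p not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing parameter columns "
                             f"{missing[:5]}...")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> List[str]:
        return sorted(self.data["group"].unique())

    def values(self, parameters: Optional[Sequence[str]] = None):
        cols = list(parameters) if parameters is not None else self.parameters
        return self.data[cols].to_numpy(dtype=float)

    def subset(self, parameters: Sequence[str]) -> "FeatureTable":
        unknown = [p for p in parameters if p not in self.parameters]
        if unknown:
            raise KeyError(f"unknown parameters {unknown}")
        cols = META_COLUMNS + list(parameters)
        return FeatureTable(data=self.data[cols].copy(),
                            parameters=list(parameters))

    def select_groups(self, groups: Sequence[str]) -> "FeatureTable":
        mask = self.data["group"].isin(list(groups))
        return FeatureTable(data=self.data[mask].reset_index(drop=True),
                            parameters=list(self.parameters))

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path,
                 parameters: Optional[Sequence[str]] = None) -> "FeatureTable":
        data = pd.read_csv(path)
        if parameters is None:
            parameters = [c for c in data.columns if c not in META_COLUMNS]
        return cls(data=data, parameters=list(parameters))
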