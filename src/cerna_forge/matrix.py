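"""Expression containers: a unit-tagged feature x sample matrix and the 3x3 design."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SampleDesign", "DEFAULT_SAMPLE_IDS"]

# sample labels follow the study's convention: 3 age groups x 3 replicates
DEFAULT_SAMPLE_IDS = (
    "A1-L", "A2-L", "A3-L",
    "B3-L", "B4-L", "B5-L",
    "C2-L", "C3-L", "C5-L",
)

VALID_UNITS = {"counts", "FPKM", "RPM", "CPM", "log2", "zscore"}


@dataclass
class SampleDesign:
    """Sample-to-group assignment; groups are age classes A/B/C with 3 replicates."""

    sample_ids: list[str]
    group_of: dict[str, str]

    def __post_init__(self):
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @classmethod
    def default(cls) -> "SampleDesign":
        ids = list(DEFAULT_SAMPLE_IDS)
        return cls(ids, {s: s[0] for s in ids})

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        out = [s for s in self.sample_ids if self.group_of[s] == group]
        if not out:
            raise ValueError(f"unknown group label: {group!r}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids,
             "group": [self.group_of[s] for s in self.sample_ids]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(list(df["sample_id"]), dict(zip(df["sample_id"], df["group"])))


@dataclass
class ExpressionMatrix:
    """Features x samples values with an explicit unit tag.

    The tag travels with the data so a screen can refuse, e.g., z-scored
    input where raw counts are required.
    """

    values: pd.DataFrame  # index: feature_ids, columns: sample_ids
    unit: str = "counts"
    feature_kind: str = ""  # informational: mRNA / lncRNA / circRNA / miRNA

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(VALID_UNITS)}")
        if self.unit in {"counts", "FPKM", "RPM", "CPM"}:
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"negative values not allowed for unit {self.unit}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def library_sizes(self) -> pd.Series:
        if self.unit != "counts":
            raise ValueError("library sizes only meaningful for raw counts")
        return self.values.sum(axis=0)

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)].copy(),
                                unit=self.unit, feature_kind=self.feature_kind)
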