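"""Expression matrices (features x samples) with explicit units and groups."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNITS = ("count", "FPKM", "TPM")


@dataclass
class ExpressionMatrix:
    """A features-by-samples matrix of non-negative expression values.

    ``groups`` maps each sample id to its group label (e.g. treatment vs
    control); unit conversions elsewhere always return a new matrix with the
    unit recorded.
    """

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    unit: str = "count"
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")
        for sample in self.groups:
            if sample not in self.values.columns:
                raise ValueError(f"group label for unknown sample {sample!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups.get(s) == group]

    def group_matrix(self, group: str) -> np.ndarray:
        cols = self.samples_in_group(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols].to_numpy(dtype=float)

    def subset(self, feature_ids: list[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[feature_ids], self.unit, dict(self.groups))

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(
    path: str | Path,
    groups: dict[str, str] | None = None,
    unit: str = "count",
) -> ExpressionMatrix:
    """Read a TSV with a feature_id column and one column per sample."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame, unit=unit, groups=groups or {})


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column sample<TAB>group file (no header)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(frame["sample"].astype(str), frame["group"].astype(str)))
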