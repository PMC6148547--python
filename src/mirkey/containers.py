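"""Shared in-memory containers for expression data.

An :class:`ExpressionStudy` is one case/control dataset: a genes x samples
DataFrame, a per-sample group label ('tumor'/'normal'), and a flag saying
whether values are already on the log2 scale. It is the unit of both the
marker meta-analysis and the DEG screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionStudy:
    study_id: str
    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> 'tumor' | 'normal'
    log2: bool = False
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError(f"{self.study_id}: samples without a group label")
        bad = set(self.groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"{self.study_id}: unknown group labels {sorted(bad)}")
        for lab in (TUMOR, NORMAL):
            if (self.groups == lab).sum() < 2:
                raise ValueError(f"{self.study_id}: fewer than 2 {lab} samples")

    @property
    def tumor_samples(self) -> pd.Index:
        return self.groups.index[self.groups == TUMOR]

    @property
    def normal_samples(self) -> pd.Index:
        return self.groups.index[self.groups == NORMAL]

    def to_log2(self, offset: float = 1.0) -> "ExpressionStudy":
        """Return a log2-scale copy (no-op if already log2)."""
        if self.log2:
            return self
        if (self.values.values < 0).any():
            raise ValueError(f"{self.study_id}: negative raw expression values")
        return ExpressionStudy(
            self.study_id,
            np.log2(self.values + offset),
            self.groups.copy(),
            log2=True,
            subgroup=self.subgroup,
        )

    def group_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        row = self.values.loc[gene]
        return row[self.tumor_samples].to_numpy(float), row[self.normal_samples].to_numpy(float)
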