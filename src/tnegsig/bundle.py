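"""Cohort container shared by every pipeline stage.

A :class:`CohortBundle` couples a log2-scale expression matrix
(features x samples) with a per-sample clinical table (DMFS time, event
flag, data source, receptor status) and an optional probe->gene-symbol
map.  Transform operations never mutate a bundle in place; they return a
new bundle carrying an appended :class:`TransformRecord` audit entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = (
    "source",
    "dmfs_months",
    "dmfs_event",
    "er_status",
    "pr_status",
    "her2_status",
)


@dataclass(frozen=True)
class TransformRecord:
    """Audit entry for one transform applied to a bundle."""

    operation: str
    params: dict[str, Any] = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "operation": self.operation,
            "params": self.params,
            "timestamp": self.timestamp,
        }


@dataclass
class CohortBundle:
    """Expression matrix + clinical outcomes + per-sample source labels.

    Parameters
    ----------
    expression
        DataFrame of log2 expression values, rows indexed by feature id
        (probe or gene symbol), columns by sample id.
    clinical
        DataFrame indexed by sample id with at least ``source``,
        ``dmfs_months`` and ``dmfs_event`` columns.  Receptor-status
        columns (``er_status``/``pr_status``/``her2_status``) hold
        ``"pos"``/``"neg"``/``"unknown"``.
    feature_map
        Optional Series mapping probe id -> gene symbol.
    transforms
        Append-only audit trail of transforms already applied.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    feature_map: pd.Series | None = None
    transforms: list[TransformRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.expression.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.clinical.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        expr_samples = set(self.expression.columns)
        clin_samples = set(self.clinical.index)
        if expr_samples != clin_samples:
            missing = expr_samples ^ clin_samples
            raise ValueError(
                f"expression/clinical sample mismatch: {sorted(missing)[:5]}"
            )
        for col in ("source", "dmfs_months", "dmfs_event"):
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        times = self.clinical["dmfs_months"].to_numpy(dtype=float)
        if np.any(times < 0) or not np.all(np.isfinite(times)):
            raise ValueError("dmfs_months must be finite and >= 0")
        events = self.clinical["dmfs_event"].to_numpy()
        if not np.isin(events, (0, 1)).all():
            raise ValueError("dmfs_event must be 0/1")

    # -- convenience accessors ------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def n_features(self) -> int:
        return self.expression.shape[0]

    @property
    def sources(self) -> list[str]:
        return sorted(self.clinical["source"].unique())

    @property
    def times(self) -> np.ndarray:
        """DMFS times in months, sample order of the expression columns."""
        return self.clinical.loc[self.expression.columns, "dmfs_months"].to_numpy(
            dtype=float
        )

    @property
    def events(self) -> np.ndarray:
        """DMFS event flags, sample order of the expression columns."""
        return self.clinical.loc[self.expression.columns, "dmfs_event"].to_numpy(
            dtype=int
        )

    def source_mask(self, source: str) -> pd.Index:
        keep = self.clinical.index[self.clinical["source"] == source]
        return self.expression.columns.intersection(keep)

    def subset_samples(self, sample_ids) -> "CohortBundle":
        wanted = set(sample_ids)
        sample_ids = [s for s in self.expression.columns if s in wanted]
        return CohortBundle(
            expression=self.expression.loc[:, sample_ids].copy(),
            clinical=self.clinical.loc[sample_ids].copy(),
            feature_map=self.feature_map,
            transforms=list(self.transforms),
        )

    def subset_features(self, feature_ids) -> "CohortBundle":
        wanted = set(feature_ids)
        feature_ids = [f for f in self.expression.index if f in wanted]
        return CohortBundle(
            expression=self.expression.loc[feature_ids].copy(),
            clinical=self.clinical.copy(),
            feature_map=self.feature_map,
            transforms=list(self.transforms),
        )

    def with_expression(
        self, expression: pd.DataFrame, record: TransformRecord | None = None
    ) -> "CohortBundle":
        transforms = list(self.transforms)
        if record is not None:
            transforms.append(record)
        return CohortBundle(
            expression=expression,
            clinical=self.clinical.copy(),
            feature_map=self.feature_map,
            transforms=transforms,
        )

    def with_clinical(
        self, clinical: pd.DataFrame, record: TransformRecord | None = None
    ) -> "CohortBundle":
        transforms = list(self.transforms)
        if record is not None:
            transforms.append(record)
        return CohortBundle(
            expression=self.expression.copy(),
            clinical=clinical,
            feature_map=self.feature_map,
            transforms=transforms,
        )
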