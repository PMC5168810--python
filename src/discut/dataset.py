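"""Core in-memory container for a two-condition expression matrix.

The package operates on a feature-by-sample matrix ``G`` (M features, N
samples) together with a binary condition label per sample.  All test
statistics ("basic attributes") are oriented group-2 minus group-1, where
group 1 and group 2 are the first and second label in sorted label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """A feature x sample expression matrix with two-condition labels.

    Parameters
    ----------
    values
        M x N matrix of expression values.  Non-negative integer counts
        for the RNA-seq extractors; any reals for the generic extractors.
    feature_ids
        M unique feature identifiers.
    sample_ids
        N sample identifiers.
    labels
        N condition codes taking exactly two distinct values.  The
        sorted-second value is "group 2"; statistics are signed
        group-2 minus group-1.
    """

    values: np.ndarray
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        m, n = self.values.shape
        if m < 1:
            raise ValueError("need at least one feature")
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{i}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{j}" for j in range(n)]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match matrix")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids must be unique")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix")
        if self.labels is None:
            raise ValueError("labels are required")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match sample count")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at feature {self.feature_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        groups = sorted(np.unique(self.labels).tolist())
        if len(groups) != 2:
            raise ValueError(f"labels must take exactly 2 values, got {groups}")
        self._groups = tuple(groups)

    # -- group structure ------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_names(self) -> tuple:
        """(group-1 label, group-2 label) in sorted label order."""
        return self._groups

    @property
    def group_mask(self) -> np.ndarray:
        """Boolean mask, True for group-2 samples."""
        return np.asarray(self.labels == self._groups[1])

    @property
    def group_sizes(self) -> tuple[int, int]:
        mask = self.group_mask
        return int((~mask).sum()), int(mask.sum())

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        """Same matrix under a different label assignment (for permutations)."""
        return ExpressionDataset(
            values=self.values,
            feature_ids=self.feature_ids,
            sample_ids=self.sample_ids,
            labels=np.asarray(labels),
        )

    def is_integer_valued(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.values - np.round(self.values)) <= tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
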