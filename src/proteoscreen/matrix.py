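"""Feature-by-sample intensity matrix with an explicit missingness mask.

The :class:`IntensityMatrix` is the object that flows through the whole
pipeline: reading, missing-value filtering, imputation, normalization,
and finally sample-level outlier screening.  Features are rows (proteins,
protein groups, metabolites); samples are columns (measurement runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix"]


@dataclass
class IntensityMatrix:
    """A feature x sample numeric table with missing entries masked out.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_features, n_samples)``.  Entries under
        the missing mask are ignored by every statistic; their stored value
        is arbitrary (NaN by convention).
    missing_mask
        Boolean array of the same shape; ``True`` marks a missing entry.
    feature_ids, sample_ids
        Unique, ordered identifiers for rows / columns.
    log_transformed
        Whether ``values`` are already on a log2 scale.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x samples)")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"mask {self.missing_mask.shape}"
            )
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != self.values.shape[0]:
            raise ValueError("feature_ids length does not match row count")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed entries must be finite")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def observed_values(self) -> np.ndarray:
        """1-D array of all observed entries."""
        return self.values[~self.missing_mask]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            list(self.feature_ids),
            list(self.sample_ids),
            self.log_transformed,
        )

    def subset_samples(self, sample_ids: list[str]) -> "IntensityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return IntensityMatrix(
            self.values[:, idx],
            self.missing_mask[:, idx],
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            self.log_transformed,
        )

    def subset_features(self, keep: np.ndarray) -> "IntensityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return IntensityMatrix(
            self.values[keep],
            self.missing_mask[keep],
            [self.feature_ids[i] for i in keep],
            list(self.sample_ids),
            self.log_transformed,
        )

    def to_frame(self) -> pd.DataFrame:
        """Features-in-rows DataFrame with NaN at missing entries."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.feature_ids, columns=self.sample_ids)

    def to_log2(self) -> "IntensityMatrix":
        """Return a log2-scale copy (identity if already log-transformed).

        Non-positive observed entries are masked as missing before the
        transform; raw MS intensities are positive by construction.
        """
        if self.log_transformed:
            return self.copy()
        mask = self.missing_mask | (self.values <= 0)
        vals = np.where(mask, np.nan, self.values)
        with np.errstate(invalid="ignore"):
            vals = np.log2(vals)
        return IntensityMatrix(
            vals, mask, list(self.feature_ids), list(self.sample_ids), True
        )

    def sample_data(self) -> np.ndarray:
        """Samples-in-rows array for detector consumption (requires no missing)."""
        if self.has_missing:
            raise ValueError("matrix still has missing values; impute first")
        return np.ascontiguousarray(self.values.T)
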