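"""Baseline univariate sample QC: identification counts, correlations, Grubbs' test.

These are the classical screens a proteomics core runs before anything
fancier: how many proteins were identified per run, and how well each run
correlates with the rest of the cohort.  Grubbs' max-deviation test flags
runs whose statistic is extreme, and the same screens feed the clean-data
curation step of the model-selection benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import IntensityMatrix

__all__ = ["SampleQCStats", "qc_stats", "grubbs_test", "GrubbsResult", "qc_table"]

MIN_SHARED_FEATURES = 3  # pairwise correlations on fewer co-observed features are undefined


@dataclass
class SampleQCStats:
    """Per-sample identification counts and mean inter-sample correlation."""

    sample_ids: list[str]
    id_count: np.ndarray          # int, features observed per sample
    mean_correlation: np.ndarray  # float, NaN where undefined
    correlation_defined: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id_count": self.id_count,
                "mean_correlation": self.mean_correlation,
                "correlation_defined": self.correlation_defined,
            },
            index=pd.Index(self.sample_ids, name="sample"),
        )


def qc_stats(m: IntensityMatrix) -> SampleQCStats:
    """Identification count and mean pairwise Pearson r (log2 scale) per sample.

    Correlations use pairwise-complete observations; a pair with fewer
    than three co-observed features contributes nothing, and a sample with
    no valid pair gets an undefined (NaN) mean correlation.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples for QC statistics")
    work = m if m.log_transformed else m.to_log2()
    id_count = (~m.missing_mask).sum(axis=0).astype(int)

    vals = np.where(work.missing_mask, np.nan, work.values)  # features x samples
    n = m.n_samples
    corr_sum = np.zeros(n)
    corr_cnt = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            if both.sum() < MIN_SHARED_FEATURES:
                continue
            x, y = vals[both, i], vals[both, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            corr_sum[i] += r
            corr_sum[j] += r
            corr_cnt[i] += 1
            corr_cnt[j] += 1
    defined = corr_cnt > 0
    mean_corr = np.full(n, np.nan)
    mean_corr[defined] = corr_sum[defined] / corr_cnt[defined]
    if not defined.all():
        bad = [m.sample_ids[i] for i in np.flatnonzero(~defined)]
        warnings.warn(f"undefined correlation for samples {bad}", stacklevel=2)
    return SampleQCStats(list(m.sample_ids), id_count, mean_corr, defined)


@dataclass
class GrubbsResult:
    """Outliers flagged by (optionally iterative) Grubbs' screening."""

    outlier_indices: list[int]
    statistics: list[float]   # G at the iteration each point was flagged
    p_values: list[float]     # max-statistic p-value at that iteration
    critical_value: float     # G_crit for the initial sample size


def _grubbs_critical(n: int, alpha: float, two_sided: bool) -> float:
    """t-quantile critical value for the max-deviation statistic."""
    denom = 2 * n if two_sided else n
    t = stats.t.ppf(1 - alpha / denom, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def _grubbs_p(g: float, n: int, two_sided: bool) -> float:
    """p-value of the observed max statistic via the inverse of the
    critical-value formula (Bonferroni-style union bound, clipped to 1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t_sq = (n - 2) * g**2 / ((n - 1) ** 2 / n - g**2)
    if not np.isfinite(t_sq) or t_sq < 0:
        return 0.0
    tail = stats.t.sf(np.sqrt(t_sq), n - 2)
    mult = 2 * n if two_sided else n
    return float(min(1.0, mult * tail))


def grubbs_test(values, alpha: float = 0.05, mode: str = "two_sided",
                iterative: bool = True) -> GrubbsResult:
    """Grubbs' max-deviation outlier test.

    Parameters
    ----------
    values
        1-D numeric data, ``n >= 3``.
    mode
        ``two_sided`` tests the most deviant point in either direction;
        ``min``/``max`` test only the smallest/largest value.
    iterative
        Remove the flagged point and repeat until no rejection.

    Returns indices into the ORIGINAL array, with the G statistic and
    max-statistic p-value at the iteration each point was flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Grubbs' test needs a 1-D sample with n >= 3")
    if mode not in ("two_sided", "min", "max"):
        raise ValueError("mode must be two_sided, min or max")
    if np.allclose(x, x[0]):
        warnings.warn("constant input: Grubbs' test flags nothing", stacklevel=2)
        return GrubbsResult([], [], [], np.nan)

    two_sided = mode == "two_sided"
    crit0 = _grubbs_critical(x.size, alpha, two_sided)
    active = np.arange(x.size)
    out_idx: list[int] = []
    out_g: list[float] = []
    out_p: list[float] = []
    while active.size >= 3:
        sub = x[active]
        mean, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            break
        if mode == "two_sided":
            local = int(np.argmax(np.abs(sub - mean)))
        elif mode == "min":
            local = int(np.argmin(sub))
        else:
            local = int(np.argmax(sub))
        g = abs(sub[local] - mean) / sd
        crit = _grubbs_critical(active.size, alpha, two_sided)
        if g <= crit:
            break
        out_idx.append(int(active[local]))
        out_g.append(float(g))
        out_p.append(_grubbs_p(g, active.size, two_sided))
        active = np.delete(active, local)
        if not iterative:
            break
    return GrubbsResult(out_idx, out_g, out_p, crit0)


def qc_table(m: IntensityMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample QC TSV content: counts, correlations, Grubbs flags."""
    s = qc_stats(m)
    flags_id = np.zeros(m.n_samples, dtype=bool)
    flags_corr = np.zeros(m.n_samples, dtype=bool)
    res_id = grubbs_test(s.id_count.astype(float), alpha=alpha)
    flags_id[res_id.outlier_indices] = True
    defined = np.flatnonzero(s.correlation_defined)
    if defined.size >= 3:
        res_corr = grubbs_test(s.mean_correlation[defined], alpha=alpha)
        flags_corr[defined[res_corr.outlier_indices]] = True
    df = s.to_frame()
    df["grubbs_flag_idcount"] = flags_id
    df["grubbs_flag_correlation"] = flags_corr
    return df
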