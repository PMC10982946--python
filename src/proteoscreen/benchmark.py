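"""Simulation-driven detector selection via gradient feature shuffling.

The selection scheme measures, for each detector configuration, how its
accuracy on simulated outliers behaves as the severity of the perturbation
grows.  Clean data are split into groups; in each trial one group's samples
have a fraction of their feature values permuted within-sample ("feature
shuffling"), the configuration is fitted on the full matrix with
contamination equal to the perturbed fraction, and classification accuracy
against the known perturbation labels is recorded.  Per configuration this
yields a proportions x groups x repeats accuracy grid; the coefficient of
variation (CV) of the accuracies per shuffle proportion is then scanned
with the Mann–Kendall trend test to find the "detection point" — the
smallest proportion from which the CV curve is trend-stable.  Finally a
vote across configurations fixes the selection criterion and configurations
that are both early-detecting and accurate are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import IntensityMatrix
from .qc import grubbs_test, qc_stats
from .registry import DetectorConfig, InfeasibleConfigError, fit_score

__all__ = [
    "TrendResult",
    "BenchmarkResult",
    "SelectionSummary",
    "curate_clean",
    "make_groups",
    "shuffle_features",
    "evaluate_config",
    "mann_kendall",
    "detection_point",
    "select_models",
    "run_benchmark",
    "DEFAULT_PROPORTIONS",
]

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))
SEQ9_FLAT_TOL = 1e-6  # two-point suffix counts as stable only if essentially flat


# ----------------------------------------------------------- clean curation

def curate_clean(m: IntensityMatrix, alpha: float = 0.05) -> IntensityMatrix:
    """Remove samples flagged by baseline QC so the benchmark start is clean.

    A sample is dropped when Grubbs' test flags its identification count
    or its mean inter-sample correlation.
    """
    if m.n_samples < 20:
        raise ValueError("clean-data curation expects >= 20 samples")
    s = qc_stats(m)
    bad = np.zeros(m.n_samples, dtype=bool)
    res_id = grubbs_test(s.id_count.astype(float), alpha=alpha)
    bad[res_id.outlier_indices] = True
    defined = np.flatnonzero(s.correlation_defined)
    if defined.size >= 3:
        res_corr = grubbs_test(s.mean_correlation[defined], alpha=alpha)
        bad[defined[res_corr.outlier_indices]] = True
    bad |= ~s.correlation_defined
    keep = [sid for sid, b in zip(m.sample_ids, bad) if not b]
    return m.subset_samples(keep)


def make_groups(sample_ids: list[str], k: int = 10, seed: int = 0) -> list[list[str]]:
    """Seeded partition into k disjoint, exhaustive, near-equal groups."""
    n = len(sample_ids)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups = np.array_split(perm, k)
    return [[sample_ids[i] for i in g] for g in groups]


# ------------------------------------------------------------- perturbation

def shuffle_features(m: IntensityMatrix, target_samples: list[str],
                     proportion: float, seed: int = 0
                     ) -> tuple[IntensityMatrix, np.ndarray]:
    """Permute a fraction of each target sample's feature values within itself.

    For each target independently, ``round(proportion * n_features)``
    features are drawn and their values permuted among themselves; the
    sample's value multiset is untouched, only the feature assignment is
    scrambled.  Returns the perturbed matrix and boolean truth labels
    (True = perturbed) aligned to ``m.sample_ids``.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    unknown = set(target_samples) - set(m.sample_ids)
    if unknown:
        raise KeyError(f"unknown target samples: {sorted(unknown)}")
    out = m.copy()
    rng = np.random.default_rng(seed)
    n_shuffle = int(round(proportion * m.n_features))
    truth = np.array([sid in set(target_samples) for sid in m.sample_ids])
    for sid in target_samples:
        j = m.sample_ids.index(sid)
        feats = rng.choice(m.n_features, size=n_shuffle, replace=False)
        perm = rng.permutation(n_shuffle)
        out.values[feats, j] = m.values[feats[perm], j]
        out.missing_mask[feats, j] = m.missing_mask[feats[perm], j]
    return out, truth


# ---------------------------------------------------------------- evaluation

def evaluate_config(
    config: DetectorConfig,
    clean: IntensityMatrix,
    groups: list[list[str]],
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    repeats: int = 10,
    seed: int = 0,
) -> np.ndarray | None:
    """Accuracy grid (n_proportions x n_groups x n_repeats) for one config.

    Each trial perturbs one group at one proportion, fits the configuration
    on the full matrix with contamination set to the true perturbed
    fraction, and scores overall classification accuracy against the
    perturbation labels.  Returns None when the configuration is
    infeasible on this data size.
    """
    n = clean.n_samples
    grid = np.full((len(proportions), len(groups), repeats), np.nan)
    for pi, prop in enumerate(proportions):
        for gi, group in enumerate(groups):
            contamination = min(0.499, max(1e-9, len(group) / n))
            for ri in range(repeats):
                trial_seed = (seed * 1000003 + pi * 10007 + gi * 101 + ri) % (2**31 - 1)
                perturbed, truth = shuffle_features(clean, group, prop, trial_seed)
                X = perturbed.sample_data()
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, flags = fit_score(config, X, contamination=contamination)
                except InfeasibleConfigError as exc:
                    logger.warning("skipping %s: %s", config.config_id, exc)
                    return None
                grid[pi, gi, ri] = (flags == truth).mean()
    return grid


# --------------------------------------------------------------- trend test

@dataclass
class TrendResult:
    """Mann–Kendall trend test outcome."""

    S: int
    var_S: float
    Z: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def mann_kendall(values) -> TrendResult:
    """Mann–Kendall trend test with tie-corrected variance.

    ``S`` sums the signs of all forward pairwise differences; its variance
    uses the tie correction ``[n(n-1)(2n+5) - sum t(t-1)(2t+5)] / 18`` over
    tie groups of size t, and the normal approximation is continuity-
    corrected: ``Z = (S - sign(S)) / sqrt(var_S)`` (0 when S = 0).  The
    p-value is two-sided.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("Mann-Kendall needs an ordered 1-D sequence, n >= 3")
    n = v.size
    diff_sign = np.sign(v[None, :] - v[:, None])
    S = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if S == 0 or var_S <= 0:
        return TrendResult(S, var_S, 0.0, 1.0)
    Z = (S - np.sign(S)) / np.sqrt(var_S)
    p = float(2.0 * norm.sf(abs(Z)))
    return TrendResult(S, var_S, float(Z), min(1.0, p))


def detection_point(cv_by_proportion,
                    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
                    alpha: float = 0.05) -> float | None:
    """Smallest shuffle proportion whose CV suffix is trend-stable.

    Suffixes start at each proportion from the first through the ninth;
    a suffix is stable when the Mann–Kendall two-sided p-value is >= alpha.
    The two-point suffix (ninth) cannot carry a trend test and counts as
    stable only when its two CVs are essentially equal.  Returns None when
    no suffix is stable.
    """
    cv = np.asarray(cv_by_proportion, dtype=float)
    if cv.size != len(proportions):
        raise ValueError(f"expected {len(proportions)} CV values, got {cv.size}")
    for start in range(len(proportions) - 1):  # suffixes of length >= 2
        suffix = cv[start:]
        if suffix.size >= 3:
            stable = mann_kendall(suffix).p_value >= alpha
        else:
            stable = abs(suffix[1] - suffix[0]) < SEQ9_FLAT_TOL
        if stable:
            return proportions[start]
    return None


# ----------------------------------------------------------------- selection

@dataclass
class BenchmarkResult:
    """Per-configuration benchmark summary."""

    config_id: str
    family: str
    accuracy: np.ndarray | None          # proportions x groups x repeats, or None
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    mean_accuracy: np.ndarray = field(default=None)  # per proportion
    cv: np.ndarray = field(default=None)             # per proportion
    detection_point: float | None = None
    accuracy_at_dp: float | None = None
    selected: bool = False

    @classmethod
    def from_grid(cls, config: DetectorConfig, grid: np.ndarray | None,
                  proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
                  ) -> "BenchmarkResult":
        res = cls(config.config_id, config.family, grid, proportions)
        if grid is None:
            return res
        flat = grid.reshape(grid.shape[0], -1)
        res.mean_accuracy = flat.mean(axis=1)
        sd = flat.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res.cv = np.where(res.mean_accuracy > 0, sd / res.mean_accuracy, np.inf)
        res.detection_point = detection_point(res.cv, proportions)
        if res.detection_point is not None:
            pi = proportions.index(res.detection_point)
            res.accuracy_at_dp = float(res.mean_accuracy[pi])
        return res


@dataclass
class SelectionSummary:
    """Outcome of the vote across configurations."""

    balance_point: float | None
    criterion: float | None
    selected_ids: list[str]
    detection_point_counts: pd.DataFrame  # per-proportion counts (summary table)


def select_models(results: list[BenchmarkResult], accuracy_threshold: float = 0.90,
                  proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
                  ) -> SelectionSummary:
    """Vote on the stable shuffle proportion and retain early, accurate configs.

    The balance point is the modal detection point across configurations
    (smallest on ties); the criterion is the next 10% node above it
    (capped at the last proportion).  A configuration is selected when its
    detection point is at or below the criterion and its mean accuracy at
    the detection point strictly exceeds the threshold.
    """
    dps = [r.detection_point for r in results if r.detection_point is not None]
    candidate_props = proportions[:-1]  # detection points live in 10%..90%
    counts = {p: 0 for p in candidate_props}
    for dp in dps:
        counts[dp] += 1
    table = pd.DataFrame(
        {"proportion": list(candidate_props),
         "n_detection_points": [counts[p] for p in candidate_props]}
    )
    if not dps:
        warnings.warn("no configuration has a detection point; empty selection",
                      stacklevel=2)
        return SelectionSummary(None, None, [], table)
    max_count = max(counts.values())
    balance = min(p for p, c in counts.items() if c == max_count)
    bi = proportions.index(balance)
    criterion = proportions[min(bi + 1, len(proportions) - 1)]
    selected = [
        r.config_id
        for r in results
        if r.detection_point is not None
        and r.detection_point <= criterion + 1e-9
        and r.accuracy_at_dp is not None
        and r.accuracy_at_dp > accuracy_threshold
    ]
    table["selected_node"] = table["proportion"] <= criterion + 1e-9
    return SelectionSummary(balance, criterion, selected, table)


def run_benchmark(
    clean: IntensityMatrix,
    registry,
    n_groups: int = 10,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    repeats: int = 10,
    seed: int = 0,
    accuracy_threshold: float = 0.90,
) -> tuple[list[BenchmarkResult], SelectionSummary]:
    """Full selection harness: groups -> accuracy grids -> trend scan -> vote."""
    groups = make_groups(list(clean.sample_ids), k=n_groups, seed=seed)
    results = []
    for cfg in registry:
        grid = evaluate_config(cfg, clean, groups, proportions, repeats, seed)
        results.append(BenchmarkResult.from_grid(cfg, grid, proportions))
    summary = select_models(results, accuracy_threshold, proportions)
    for r in results:
        r.selected = r.config_id in set(summary.selected_ids)
    return results, summary


def results_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Long-format per-config mean accuracy and CV per proportion."""
    rows = []
    for r in results:
        if r.mean_accuracy is None:
            continue
        for p, acc, cv in zip(r.proportions, r.mean_accuracy, r.cv):
            rows.append({"config_id": r.config_id, "family": r.family,
                         "proportion": p, "mean_accuracy": acc, "cv": cv})
    return pd.DataFrame(rows)
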