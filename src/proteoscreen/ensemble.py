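"""Multi-round subsample voting and chi-square confirmation of outlier samples.

Each resampling round draws a fraction of the samples without replacement,
fits every detector configuration on the subset and flags outliers within
it.  Per configuration, a sample is voted an outlier when it was flagged in
a majority of the rounds that contained it; the per-sample vote totals over
all configurations form the :class:`VoteTable`.  Samples with an outlier
majority enter the candidate pool and are confirmed by a one-degree-of-
freedom chi-square goodness-of-fit test against an even vote split.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .detectors import DistanceCache
from .matrix import IntensityMatrix
from .registry import InfeasibleConfigError, ModelRegistry, fit_score

__all__ = [
    "VoteTable",
    "OutlierReport",
    "run_ensemble",
    "candidate_pool",
    "chi_square_confirm",
    "build_report",
    "significance_stars",
]

logger = logging.getLogger(__name__)


@dataclass
class VoteTable:
    """Per-sample outlier/normal vote counts aggregated over configurations.

    ``rounds_seen``/``rounds_flagged`` record, per (config, sample), how
    many rounds contained the sample and how often it was flagged there.
    ``score_sum``/``score_count`` accumulate min-max normalized raw scores
    over rounds, for downstream confidence visualization.
    """

    sample_ids: list[str]
    config_ids: list[str]
    families: list[str]
    rounds_seen: np.ndarray      # (n_configs, n_samples) int
    rounds_flagged: np.ndarray   # (n_configs, n_samples) int
    score_sum: np.ndarray        # (n_configs, n_samples) float
    score_count: np.ndarray      # (n_configs, n_samples) int
    n_rounds: int
    subsample_frac: float

    @property
    def n_models(self) -> int:
        return len(self.config_ids)

    @property
    def model_votes(self) -> np.ndarray:
        """(n_configs, n_samples) bool: per-config majority-over-rounds vote."""
        return self.rounds_flagged * 2 > self.rounds_seen

    @property
    def outlier_votes(self) -> np.ndarray:
        return self.model_votes.sum(axis=0).astype(int)

    @property
    def normal_votes(self) -> np.ndarray:
        return self.n_models - self.outlier_votes

    def votes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"outlier_votes": self.outlier_votes, "normal_votes": self.normal_votes},
            index=pd.Index(self.sample_ids, name="sample"),
        )


def _round_seed(master_seed: int, round_idx: int) -> int:
    # fixed offsets so adding rounds never perturbs earlier rounds
    return (int(master_seed) * 100003 + round_idx) % (2**31 - 1)


def run_ensemble(
    m: IntensityMatrix,
    registry: ModelRegistry,
    n_rounds: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> VoteTable:
    """Vote on outlier status over ``n_rounds`` random subsample rounds.

    Parameters
    ----------
    m
        A fully imputed/normalized matrix (no missing entries).
    registry
        Detector configurations to run; each contributes one vote per sample.
    n_rounds
        Number of subsampling rounds.
    subsample_frac
        Fraction of samples drawn (without replacement) each round; the
        subset size is ``ceil(frac * n)``.
    seed
        Master seed; per-round draws come from fixed-offset substreams.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must be in (0, 1]")
    if m.has_missing:
        raise ValueError("matrix has missing values; run preprocessing first")

    X_all = m.sample_data()  # samples x features
    n = X_all.shape[0]
    n_sub = math.ceil(subsample_frac * n)
    n_cfg = len(registry)
    configs = list(registry)

    rounds_seen = np.zeros((n_cfg, n), dtype=int)
    rounds_flagged = np.zeros((n_cfg, n), dtype=int)
    score_sum = np.zeros((n_cfg, n))
    score_count = np.zeros((n_cfg, n), dtype=int)
    skipped: dict[str, int] = {}

    for r in range(n_rounds):
        rng = np.random.default_rng(_round_seed(seed, r))
        subset = np.sort(rng.choice(n, size=n_sub, replace=False))
        X = X_all[subset]
        cache = DistanceCache(X)
        for ci, cfg in enumerate(configs):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores, flags = fit_score(cfg, X, cache=cache)
            except InfeasibleConfigError as exc:
                skipped[cfg.config_id] = skipped.get(cfg.config_id, 0) + 1
                logger.warning("round %d: skipping %s (%s)", r, cfg.config_id, exc)
                continue
            rounds_seen[ci, subset] += 1
            rounds_flagged[ci, subset] += flags.astype(int)
            lo, hi = scores.min(), scores.max()
            norm = (scores - lo) / (hi - lo) if hi > lo else np.zeros_like(scores)
            score_sum[ci, subset] += norm
            score_count[ci, subset] += 1

    never_seen = np.flatnonzero(rounds_seen.max(axis=0) == 0)
    if never_seen.size:
        missing = [m.sample_ids[i] for i in never_seen]
        raise RuntimeError(
            f"samples never drawn in any round: {missing}; raise n_rounds"
        )
    if skipped:
        logger.info("skipped configs (rounds): %s", skipped)

    return VoteTable(
        sample_ids=list(m.sample_ids),
        config_ids=[c.config_id for c in configs],
        families=[c.family for c in configs],
        rounds_seen=rounds_seen,
        rounds_flagged=rounds_flagged,
        score_sum=score_sum,
        score_count=score_count,
        n_rounds=n_rounds,
        subsample_frac=subsample_frac,
    )


def candidate_pool(votes: VoteTable) -> list[str]:
    """Samples with an outlier-vote majority, most-voted first."""
    ov, nv = votes.outlier_votes, votes.normal_votes
    idx = np.flatnonzero(ov > nv)
    order = idx[np.argsort(-ov[idx], kind="stable")]
    return [votes.sample_ids[i] for i in order]


def chi_square_confirm(outlier_votes: int, normal_votes: int,
                       alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-df goodness-of-fit of the vote split against a 50/50 expectation.

    ``chi2 = (a - b)^2 / (a + b)`` with no continuity correction; the
    p-value is the upper tail of the chi-square(1) distribution.  A sample
    is confirmed when ``p < alpha`` *and* the outlier votes are in the
    majority.
    """
    a, b = int(outlier_votes), int(normal_votes)
    if a < 0 or b < 0:
        raise ValueError("vote counts must be non-negative")
    total = a + b
    if total < 1:
        raise ValueError("need at least one vote")
    chi2 = (a - b) ** 2 / total
    p = float(chi2_dist.sf(chi2, df=1))
    confirmed = bool(p < alpha and a > b)
    return float(chi2), p, confirmed


def significance_stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass
class OutlierReport:
    """Chi-square confirmation results for the candidate pool."""

    candidates: pd.DataFrame      # sample, outlier_votes, normal_votes, chi2, p, confirmed, stars
    non_candidates: pd.DataFrame  # sample, outlier_votes, normal_votes
    alpha: float

    @property
    def confirmed_outliers(self) -> list[str]:
        if self.candidates.empty:
            return []
        return self.candidates.loc[self.candidates["confirmed"], "sample"].tolist()

    def to_tsv(self, path: str) -> None:
        frame = self.candidates.copy()
        if self.non_candidates.size:
            extra = self.non_candidates.copy()
            extra["chi2"] = np.nan
            extra["p_value"] = np.nan
            extra["confirmed"] = False
            extra["stars"] = ""
            frame = pd.concat([frame, extra], ignore_index=True)
        frame.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str) -> None:
        payload = {
            "alpha": self.alpha,
            "candidates": self.candidates.to_dict(orient="records"),
            "non_candidates": self.non_candidates.to_dict(orient="records"),
            "confirmed_outliers": self.confirmed_outliers,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def build_report(votes: VoteTable, alpha: float = 0.05) -> OutlierReport:
    """Chi-square confirmation for every candidate; others listed with votes only."""
    ov, nv = votes.outlier_votes, votes.normal_votes
    cand_ids = candidate_pool(votes)
    cand_set = set(cand_ids)
    rows = []
    for sid in cand_ids:
        i = votes.sample_ids.index(sid)
        chi2, p, confirmed = chi_square_confirm(ov[i], nv[i], alpha)
        rows.append({
            "sample": sid, "outlier_votes": int(ov[i]), "normal_votes": int(nv[i]),
            "chi2": chi2, "p_value": p, "confirmed": confirmed,
            "stars": significance_stars(p),
        })
    columns = ["sample", "outlier_votes", "normal_votes", "chi2", "p_value",
               "confirmed", "stars"]
    candidates = pd.DataFrame(rows, columns=columns)
    other = [
        {"sample": s, "outlier_votes": int(ov[i]), "normal_votes": int(nv[i])}
        for i, s in enumerate(votes.sample_ids) if s not in cand_set
    ]
    non_candidates = pd.DataFrame(other, columns=["sample", "outlier_votes",
                                                  "normal_votes"])
    return OutlierReport(candidates, non_candidates, alpha)
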