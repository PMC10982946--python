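"""Seeded generator of proteomics-like intensity matrices with planted outliers.

Base intensities are log-normal: log2 intensities are Gaussian around
per-feature means, with block-correlated features (shared per-sample latent
factor within each block) mimicking co-regulated protein modules.
Missingness is missing-not-at-random: the dropout probability rises as the
(log) intensity falls, with the logistic threshold calibrated so the
realized missing fraction matches the request.  Outlier samples are planted
by one of three mechanisms:

``shift``
    A random half of the features is shifted by ±magnitude standard
    deviations (sign drawn per feature).  Signs and feature subsets are
    random so the perturbation scrambles the sample's rank structure —
    a uniform all-feature shift would be invisible after quantile
    normalization.
``noise``
    The sample's residuals around the feature means are inflated by the
    magnitude factor.
``shuffle``
    Within-sample feature permutation at proportion = magnitude, as in the
    benchmark's feature shuffling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix import IntensityMatrix

__all__ = ["SyntheticDataset", "generate", "write_fixture"]

BLOCK_SIZE = 20
BLOCK_CORRELATION = 0.6
# typical log2 LFQ intensity location/spread for a deep proteome
MEAN_LOG2 = 25.0
BETWEEN_FEATURE_SD = 2.0
WITHIN_FEATURE_SD = 1.0
MNAR_SCALE = 1.0  # logistic steepness of dropout vs log2 intensity

MECHANISMS = ("shift", "noise", "shuffle")


@dataclass
class SyntheticDataset:
    """Generated matrix plus ground truth and a perturbation log."""

    matrix: IntensityMatrix
    truth: np.ndarray          # bool per sample, True = planted outlier
    mechanism_log: list[dict]  # one entry per outlier
    seed: int

    @property
    def outlier_ids(self) -> list[str]:
        return [s for s, t in zip(self.matrix.sample_ids, self.truth) if t]


def generate(
    n_samples: int = 60,
    n_features: int = 200,
    outlier_frac: float = 0.05,
    mechanism: str = "shift",
    magnitude: float = 6.0,
    missing_frac: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a log2-scale intensity matrix with planted outlier samples.

    Parameters
    ----------
    outlier_frac
        Fraction of samples planted as outliers, in [0, 0.5); the planted
        count is ``round(outlier_frac * n_samples)``.
    mechanism, magnitude
        Perturbation type and severity: sd units for ``shift``, variance
        inflation factor for ``noise``, shuffle proportion for ``shuffle``.
    missing_frac
        Target overall missing fraction, in [0, 0.75), realized MNAR.
    """
    if not 0.0 <= outlier_frac < 0.5:
        raise ValueError("outlier_frac must be in [0, 0.5)")
    if not 0.0 <= missing_frac < 0.75:
        raise ValueError("missing_frac must be in [0, 0.75)")
    if mechanism not in MECHANISMS:
        raise ValueError(f"mechanism must be one of {MECHANISMS}")
    rng = np.random.default_rng(seed)

    feat_means = rng.normal(MEAN_LOG2, BETWEEN_FEATURE_SD, size=n_features)
    n_blocks = int(np.ceil(n_features / BLOCK_SIZE))
    block_of = np.repeat(np.arange(n_blocks), BLOCK_SIZE)[:n_features]
    latent = rng.normal(size=(n_blocks, n_samples))          # per-block sample factor
    noise = rng.normal(size=(n_features, n_samples))
    r = BLOCK_CORRELATION
    resid = np.sqrt(r) * latent[block_of] + np.sqrt(1 - r) * noise
    values = feat_means[:, None] + WITHIN_FEATURE_SD * resid  # features x samples

    n_out = int(round(outlier_frac * n_samples))
    outlier_idx = rng.choice(n_samples, size=n_out, replace=False)
    truth = np.zeros(n_samples, dtype=bool)
    truth[outlier_idx] = True
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    feature_ids = [f"P{i + 1:05d}" for i in range(n_features)]

    log = []
    for j in outlier_idx:
        if mechanism == "shift":
            feats = rng.choice(n_features, size=n_features // 2, replace=False)
            signs = rng.choice([-1.0, 1.0], size=feats.size)
            values[feats, j] += signs * magnitude * WITHIN_FEATURE_SD
            log.append({"sample": sample_ids[j], "mechanism": "shift",
                        "magnitude": magnitude, "n_features": int(feats.size)})
        elif mechanism == "noise":
            values[:, j] = feat_means + magnitude * WITHIN_FEATURE_SD * resid[:, j]
            log.append({"sample": sample_ids[j], "mechanism": "noise",
                        "magnitude": magnitude, "n_features": n_features})
        else:  # shuffle
            n_shuf = int(round(magnitude * n_features))
            feats = rng.choice(n_features, size=n_shuf, replace=False)
            perm = rng.permutation(n_shuf)
            values[feats, j] = values[feats[perm], j]
            log.append({"sample": sample_ids[j], "mechanism": "shuffle",
                        "magnitude": magnitude, "n_features": n_shuf})

    mask = _mnar_mask(values, missing_frac, rng)
    vals = values.copy()
    vals[mask] = np.nan
    matrix = IntensityMatrix(vals, mask, feature_ids, sample_ids, log_transformed=True)
    return SyntheticDataset(matrix, truth, log, seed)


def _mnar_mask(values: np.ndarray, missing_frac: float,
               rng: np.random.Generator) -> np.ndarray:
    """Intensity-dependent dropout calibrated to the requested overall rate."""
    if missing_frac <= 0:
        return np.zeros(values.shape, dtype=bool)

    def mean_prob(threshold: float) -> float:
        p = 1.0 / (1.0 + np.exp((values - threshold) / MNAR_SCALE))
        return float(p.mean())

    lo, hi = values.min() - 50, values.max() + 50
    threshold = brentq(lambda t: mean_prob(t) - missing_frac, lo, hi, xtol=1e-6)
    p_miss = 1.0 / (1.0 + np.exp((values - threshold) / MNAR_SCALE))
    return rng.random(values.shape) < p_miss


def write_fixture(ds: SyntheticDataset, out_dir: str) -> dict[str, str]:
    """Write matrix TSV, truth TSV and a MaxQuant-dialect proteinGroups.txt.

    The matrix TSV round-trips bit-exactly through ``read_matrix``; the
    proteinGroups file (linear-scale LFQ columns, zeros at missing cells)
    parses through ``read_maxquant``.
    """
    os.makedirs(out_dir, exist_ok=True)
    m = ds.matrix
    paths = {
        "matrix": os.path.join(out_dir, "matrix.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "proteingroups": os.path.join(out_dir, "proteinGroups.txt"),
    }
    df = m.to_frame()
    df.to_csv(paths["matrix"], sep="\t", na_rep="", index_label="feature")

    pd.DataFrame({
        "sample": m.sample_ids,
        "label": ["outlier" if t else "normal" for t in ds.truth],
    }).to_csv(paths["truth"], sep="\t", index=False)

    linear = np.where(m.missing_mask, 0.0, np.power(2.0, m.values))
    pg = pd.DataFrame({"Protein IDs": m.feature_ids})
    for j, sid in enumerate(m.sample_ids):
        pg[f"LFQ intensity {sid}"] = linear[:, j]
    pg["Reverse"] = ""
    pg["Potential contaminant"] = ""
    pg["Only identified by site"] = ""
    pg.to_csv(paths["proteingroups"], sep="\t", index=False)
    return paths
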