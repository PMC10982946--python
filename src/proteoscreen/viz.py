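"""Confidence-space visualization: joint decision boundaries and vote bars.

Each detector family's raw scores are min-max normalized over samples and
averaged across the family's configurations, placing every sample in a
per-family confidence space in [0, 1].  Pairs of families span a 2-D plane
where the ensemble's decision boundary can be drawn as an interpolated
confidence gradient, with confirmed outliers and normal samples marked
differently.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ensemble import OutlierReport, VoteTable

__all__ = ["confidence_table", "boundary_plot", "vote_bar_plot"]


def confidence_table(votes: VoteTable) -> pd.DataFrame:
    """Per-sample, per-family mean normalized outlier score plus ensemble confidence.

    A configuration's score for a sample is its mean min-max-normalized
    score over the rounds that contained the sample; family columns average
    those over the family's configurations.  Families that never produced
    a score are omitted with a warning.  Constant score vectors normalize
    to zero.
    """
    fam_order = list(dict.fromkeys(votes.families))
    n = len(votes.sample_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_config = np.where(votes.score_count > 0,
                              votes.score_sum / np.maximum(votes.score_count, 1),
                              np.nan)
    cols: dict[str, np.ndarray] = {}
    for fam in fam_order:
        rows = [i for i, f in enumerate(votes.families) if f == fam]
        block = per_config[rows]
        if np.all(np.isnan(block)):
            warnings.warn(f"family {fam} produced no scores; omitted", stacklevel=2)
            continue
        # min-max per config over samples, then average over family configs
        lo = np.nanmin(block, axis=1, keepdims=True)
        hi = np.nanmax(block, axis=1, keepdims=True)
        span = hi - lo
        normed = np.where(span > 0, (block - lo) / np.where(span > 0, span, 1.0), 0.0)
        cols[fam] = np.nanmean(normed, axis=0)
    df = pd.DataFrame(cols, index=pd.Index(votes.sample_ids, name="sample"))
    df["ensemble_confidence"] = votes.outlier_votes / votes.n_models
    return df


def boundary_plot(table: pd.DataFrame, family_x: str, family_y: str,
                  out: str, *, report: OutlierReport | None = None,
                  grid_size: int = 100) -> str:
    """Scatter samples in a two-family confidence plane and write an image.

    The background is an inverse-distance-weighted interpolation of the
    per-sample ensemble confidence; confirmed outliers are drawn as
    circles, other samples as squares.  The plotted coordinates are also
    written next to the image as TSV so the rendering is auditable.
    """
    for fam in (family_x, family_y):
        if fam not in table.columns:
            raise KeyError(f"family {fam!r} not present in confidence table")
    if len(table) < 2:
        raise ValueError("need at least 2 samples to plot")
    x = table[family_x].to_numpy()
    y = table[family_y].to_numpy()
    conf = table["ensemble_confidence"].to_numpy()
    outliers = set(report.confirmed_outliers) if report is not None else set()
    is_out = np.array([s in outliers for s in table.index])

    gx, gy = np.meshgrid(np.linspace(0, 1, grid_size), np.linspace(0, 1, grid_size))
    d2 = (gx[..., None] - x) ** 2 + (gy[..., None] - y) ** 2
    w = 1.0 / (d2 + 1e-6)
    backdrop = (w * conf).sum(axis=-1) / w.sum(axis=-1)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(backdrop, origin="lower", extent=(0, 1, 0, 1), cmap="RdBu_r",
                   vmin=0, vmax=1, alpha=0.6, aspect="auto")
    ax.scatter(x[~is_out], y[~is_out], marker="s", c="white", edgecolors="black",
               s=40, label="normal")
    if is_out.any():
        ax.scatter(x[is_out], y[is_out], marker="o", c="crimson",
                   edgecolors="black", s=60, label="outlier")
    ax.set_xlabel(f"{family_x} confidence")
    ax.set_ylabel(f"{family_y} confidence")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left")
    fig.colorbar(im, ax=ax, label="ensemble confidence")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)

    tsv = out.rsplit(".", 1)[0] + ".tsv"
    table[[family_x, family_y, "ensemble_confidence"]].to_csv(tsv, sep="\t")
    return out


def vote_bar_plot(report: OutlierReport, out: str) -> str:
    """Candidate vote bars annotated with chi-square significance stars."""
    df = report.candidates
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * max(len(df), 1) + 2), 4))
    if df.empty:
        ax.text(0.5, 0.5, "no candidate outliers", ha="center", va="center")
    else:
        xs = np.arange(len(df))
        ax.bar(xs - 0.2, df["outlier_votes"], width=0.4, label="outlier votes")
        ax.bar(xs + 0.2, df["normal_votes"], width=0.4, label="normal votes")
        for i, row in df.reset_index().iterrows():
            ax.text(i, max(row["outlier_votes"], row["normal_votes"]) + 0.5,
                    row["stars"], ha="center")
        ax.set_xticks(xs, df["sample"], rotation=45, ha="right")
        ax.legend()
    ax.set_ylabel("votes")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
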