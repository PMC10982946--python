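"""End-to-end orchestration: preprocess -> vote -> confirm, per sample group."""

from __future__ import annotations

from dataclasses import dataclass

from .ensemble import OutlierReport, VoteTable, build_report, run_ensemble
from .matrix import IntensityMatrix
from .preprocess import filter_missing_features, impute_minimum, normalize
from .registry import ModelRegistry, build_selected_registry

__all__ = ["DetectResult", "detect"]


@dataclass
class DetectResult:
    """Per-group vote tables and confirmation reports."""

    votes: dict[str, VoteTable]     # group label -> VoteTable
    reports: dict[str, OutlierReport]

    @property
    def confirmed_outliers(self) -> list[str]:
        out: list[str] = []
        for rep in self.reports.values():
            out.extend(rep.confirmed_outliers)
        return out


def detect(
    m: IntensityMatrix,
    registry: ModelRegistry | None = None,
    *,
    labels: dict[str, str] | None = None,
    max_missing_frac: float = 0.75,
    normalization: str = "quantile",
    n_rounds: int = 100,
    subsample_frac: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> DetectResult:
    """Run the full screening pipeline on a raw intensity matrix.

    When ``labels`` maps sample ids to group names (e.g. tumor vs normal
    adjacent tissue), each group is preprocessed and screened completely
    independently and reports never mix groups.
    """
    if registry is None:
        registry = build_selected_registry()
    if labels is None:
        groups = {"all": list(m.sample_ids)}
    else:
        missing = set(m.sample_ids) - set(labels)
        if missing:
            raise KeyError(f"samples without a group label: {sorted(missing)[:5]}")
        groups = {}
        for sid in m.sample_ids:  # preserve sample order within groups
            groups.setdefault(labels[sid], []).append(sid)

    votes: dict[str, VoteTable] = {}
    reports: dict[str, OutlierReport] = {}
    for gname, sids in groups.items():
        sub = m.subset_samples(sids)
        sub = filter_missing_features(sub, max_missing_frac)
        sub = impute_minimum(sub)
        sub = normalize(sub, normalization)
        vt = run_ensemble(sub, registry, n_rounds=n_rounds,
                          subsample_frac=subsample_frac, seed=seed)
        votes[gname] = vt
        reports[gname] = build_report(vt, alpha=alpha)
    return DetectResult(votes, reports)
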