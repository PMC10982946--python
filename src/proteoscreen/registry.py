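"""The detector pool: configuration grids, enumeration and a uniform fit/score API.

Ten unsupervised detector families are enumerated over fixed hyperparameter
grids into 170 default configurations:

======  =====================================================  =====
family  grid                                                   count
======  =====================================================  =====
LOF     5 neighbour counts x 3 metrics                            15
KNN     10 neighbour counts x 3 metrics                           30
AvgKNN  10 neighbour counts x 3 metrics                           30
CBLOF   5 cluster counts x 3 seeds                                15
OCSVM   3 kernels x 5 nu values                                   15
ABOD    15 neighbour counts                                       15
ECOD    5 contamination levels                                     5
IForest 5 tree counts x 3 seeds                                   15
FeatB   3 estimator counts x 5 seeds (LOF base)                   15
LSCP    3 pool sizes x 5 seeds (LOF/KNN pool)                     15
======  =====================================================  =====

A curated 91-config subset spanning seven families (all LOF, CBLOF,
FeatureBagging and LSCP configs, 10 KNN, 16 AvgKNN and 5 OCSVM configs)
ships with the package and is the default pool for screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import detectors as det

__all__ = [
    "DetectorConfig",
    "ModelRegistry",
    "InfeasibleConfigError",
    "build_default_registry",
    "build_selected_registry",
    "load_selection_ids",
    "fit_score",
    "FAMILIES",
]

FAMILIES = ("LOF", "KNN", "AvgKNN", "CBLOF", "OCSVM", "ABOD", "ECOD",
            "IForest", "FeatureBagging", "LSCP")

_VALID_METRICS = ("euclidean", "manhattan", "chebyshev")
_VALID_KERNELS = ("rbf", "sigmoid", "poly")

DEFAULT_CONTAMINATION = 0.1


class InfeasibleConfigError(ValueError):
    """A configuration cannot run on the given data size (e.g. k >= n)."""


@dataclass(frozen=True)
class DetectorConfig:
    """One detector family + hyperparameters + contamination + seed."""

    config_id: str
    family: str
    hyperparameters: dict
    contamination: float = DEFAULT_CONTAMINATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        if not 0.0 < self.contamination < 0.5:
            raise ValueError("contamination must be in (0, 0.5)")
        hp = self.hyperparameters
        if "n_neighbors" in hp and hp["n_neighbors"] < 1:
            raise ValueError("n_neighbors must be >= 1")
        if "metric" in hp and hp["metric"] not in _VALID_METRICS:
            raise ValueError(f"metric must be one of {_VALID_METRICS}")
        if "kernel" in hp and hp["kernel"] not in _VALID_KERNELS:
            raise ValueError(f"kernel must be one of {_VALID_KERNELS}")

    def min_samples(self) -> int:
        """Smallest dataset this configuration can be fitted on."""
        hp = self.hyperparameters
        need = 5
        if "n_neighbors" in hp:
            need = max(need, hp["n_neighbors"] + 1)
        if self.family == "CBLOF":
            need = max(need, hp.get("n_clusters", 8))
        if self.family == "LSCP":
            # ladder neighbour counts grow as 5,5,10,10,15,15,20,20,...
            pool = hp.get("pool_size", 6)
            ladder_max = 5 * ((pool + 1) // 2)
            need = max(need, hp.get("local_k", 10) + 1, ladder_max + 1)
        return need

    def to_dict(self) -> dict:
        return {
            "config_id": self.config_id,
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "contamination": self.contamination,
            "seed": self.seed,
        }


@dataclass
class ModelRegistry:
    """Ordered collection of detector configurations."""

    configs: list[DetectorConfig]
    name: str = "registry"

    def __post_init__(self) -> None:
        ids = [c.config_id for c in self.configs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate config_id in registry")

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)

    def __getitem__(self, config_id: str) -> DetectorConfig:
        for c in self.configs:
            if c.config_id == config_id:
                return c
        raise KeyError(config_id)

    @property
    def config_ids(self) -> list[str]:
        return [c.config_id for c in self.configs]

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.configs:
            counts[c.family] = counts.get(c.family, 0) + 1
        return counts

    # ------------------------------------------------------------ serialize
    def to_yaml(self, path: str) -> None:
        payload = {"version": 1, "name": self.name,
                   "configs": [c.to_dict() for c in self.configs]}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelRegistry":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        configs = [DetectorConfig(**c) for c in payload["configs"]]
        return cls(configs, name=payload.get("name", "registry"))


# --------------------------------------------------------------- enumeration

def _enumerate_default() -> list[DetectorConfig]:
    configs: list[DetectorConfig] = []

    def add(family: str, tag: str, hp: dict, seed: int = 0,
            contamination: float = DEFAULT_CONTAMINATION) -> None:
        configs.append(DetectorConfig(f"{family}_{tag}", family, hp,
                                      contamination, seed))

    for k in (5, 10, 15, 20, 25):
        for metric in _VALID_METRICS:
            add("LOF", f"k{k}_{metric}", {"n_neighbors": k, "metric": metric})
    knn_ks = (3, 5, 8, 10, 15, 20, 25, 30, 40, 50)
    for k in knn_ks:
        for metric in _VALID_METRICS:
            add("KNN", f"k{k}_{metric}", {"n_neighbors": k, "metric": metric})
    for k in knn_ks:
        for metric in _VALID_METRICS:
            add("AvgKNN", f"k{k}_{metric}", {"n_neighbors": k, "metric": metric})
    for c in (4, 6, 8, 10, 12):
        for s in range(3):
            add("CBLOF", f"c{c}_s{s}", {"n_clusters": c}, seed=s)
    for kernel in _VALID_KERNELS:
        for nu in (0.05, 0.1, 0.2, 0.3, 0.4):
            add("OCSVM", f"{kernel}_nu{nu}", {"kernel": kernel, "nu": nu})
    for k in (3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 25, 30):
        add("ABOD", f"k{k}", {"n_neighbors": k})
    for cont in (0.05, 0.1, 0.15, 0.2, 0.25):
        add("ECOD", f"c{cont}", {}, contamination=cont)
    for t in (50, 100, 150, 200, 300):
        for s in range(3):
            add("IForest", f"t{t}_s{s}", {"n_estimators": t}, seed=s)
    for e in (5, 10, 15):
        for s in range(5):
            add("FeatureBagging", f"e{e}_s{s}", {"n_estimators": e}, seed=s)
    for p in (4, 6, 8):
        for s in range(5):
            add("LSCP", f"p{p}_s{s}", {"pool_size": p}, seed=s)
    return configs


def build_default_registry(contamination: float = DEFAULT_CONTAMINATION) -> ModelRegistry:
    """Enumerate the full 170-configuration pool (deterministic, no RNG).

    ``contamination`` overrides the flagging fraction for every family
    except ECOD, whose grid is the contamination level itself.
    """
    configs = _enumerate_default()
    if contamination != DEFAULT_CONTAMINATION:
        configs = [
            c if c.family == "ECOD" else DetectorConfig(
                c.config_id, c.family, c.hyperparameters, contamination, c.seed)
            for c in configs
        ]
    return ModelRegistry(configs, name="default-170")


def build_selected_registry(selection: list[str] | None = None,
                            contamination: float = DEFAULT_CONTAMINATION) -> ModelRegistry:
    """Subset of the default registry, preserving enumeration order.

    With no argument, the shipped 91-config selection spanning seven
    families is used.
    """
    if selection is None:
        selection = load_selection_ids()
    default = build_default_registry(contamination)
    known = set(default.config_ids)
    unknown = [s for s in selection if s not in known]
    if unknown:
        raise KeyError(f"unknown config ids: {unknown[:5]}")
    if not selection:
        warnings.warn("empty selection: registry has no configs", stacklevel=2)
    wanted = set(selection)
    configs = [c for c in default if c.config_id in wanted]
    return ModelRegistry(configs, name="selected")


def load_selection_ids() -> list[str]:
    """Config ids of the shipped default selection (91 configs, 7 families)."""
    ref = resources.files("proteoscreen").joinpath("data/selection_91.synthetic.yaml")
    payload = yaml.safe_load(ref.read_text())
    return list(payload["selection"])


# ----------------------------------------------------------------- fit/score

_SCORERS = {
    "LOF": det.score_lof,
    "KNN": det.score_knn,
    "AvgKNN": det.score_avg_knn,
    "CBLOF": det.score_cblof,
    "OCSVM": det.score_ocsvm,
    "ABOD": det.score_abod,
    "ECOD": det.score_ecod,
    "IForest": det.score_iforest,
    "FeatureBagging": det.score_feature_bagging,
    "LSCP": det.score_lscp,
}

_CACHED_FAMILIES = {"LOF", "KNN", "AvgKNN", "ABOD", "LSCP"}


def fit_score(config: DetectorConfig, data: np.ndarray, *,
              cache: det.DistanceCache | None = None,
              contamination: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fit one configuration on a samples x features array and score it.

    Returns ``(raw_scores, flags)`` with one entry per sample; higher score
    means more outlying, and flags mark scores above the configuration's
    contamination quantile.  Deterministic given ``config.seed``.

    Raises
    ------
    InfeasibleConfigError
        If the data has fewer samples than the configuration needs
        (callers typically skip the config for that subset).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be samples x features")
    n = X.shape[0]
    if n < 5:
        raise InfeasibleConfigError(f"need >= 5 samples, have {n}")
    if n < config.min_samples():
        raise InfeasibleConfigError(
            f"{config.config_id} needs >= {config.min_samples()} samples, have {n}"
        )
    cont = config.contamination if contamination is None else contamination
    if np.allclose(X, X[0]):
        warnings.warn(f"{config.config_id}: degenerate data (zero variance); "
                      "no outliers flagged", stacklevel=2)
        return np.zeros(n), np.zeros(n, dtype=bool)

    kwargs = dict(config.hyperparameters)
    if config.family in ("CBLOF", "IForest", "FeatureBagging", "LSCP"):
        kwargs["seed"] = config.seed
    if config.family in _CACHED_FAMILIES and cache is not None:
        kwargs["cache"] = cache
    scores = _SCORERS[config.family](X, **kwargs)
    flags = det.flags_from_scores(scores, cont)
    return scores, flags
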