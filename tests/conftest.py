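import numpy as np
import pytest

from proteoscreen import DetectorConfig, IntensityMatrix, ModelRegistry, generate


@pytest.fixture
def small_matrix() -> IntensityMatrix:
    """4 features x 5 samples, log2 scale, one missing entry."""
    rng = np.random.default_rng(7)
    values = rng.normal(25, 1, size=(4, 5))
    mask = np.zeros((4, 5), dtype=bool)
    mask[1, 2] = True
    values[mask] = np.nan
    return IntensityMatrix(values, mask,
                           [f"P{i}" for i in range(4)],
                           [f"S{i}" for i in range(5)],
                           log_transformed=True)


@pytest.fixture
def synthetic_dataset():
    """60 samples x 200 features, 3 strong planted mean-shift outliers."""
    return generate(n_samples=60, n_features=200, outlier_frac=0.05,
                    mechanism="shift", magnitude=6.0, missing_frac=0.1, seed=11)


@pytest.fixture(scope="session")
def tiny_registry() -> ModelRegistry:
    """Three cheap configs for fast ensemble exercises."""
    return ModelRegistry([
        DetectorConfig("KNN_k3_euclidean", "KNN",
                       {"n_neighbors": 3, "metric": "euclidean"}),
        DetectorConfig("AvgKNN_k3_euclidean", "AvgKNN",
                       {"n_neighbors": 3, "metric": "euclidean"}),
        DetectorConfig("LOF_k5_euclidean", "LOF",
                       {"n_neighbors": 5, "metric": "euclidean"}),
    ], name="tiny")


MAXQUANT_HEADER = [
    "Protein IDs", "Reverse", "Potential contaminant", "Only identified by site",
    "LFQ intensity A", "LFQ intensity B", "Intensity A", "Intensity B",
]

MAXQUANT_ROWS = [
    ["PG1", "", "", "", "1000", "2000", "1100", "2100"],
    ["PG2", "+", "", "", "500", "600", "550", "650"],      # reverse decoy
    ["PG3", "", "+", "", "700", "800", "750", "850"],      # contaminant
    ["PG4", "", "", "", "0", "900", "10", "950"],          # zero -> missing
    ["PG5", "", "", "", "300", "400", "310", "410"],
]


@pytest.fixture
def maxquant_file(tmp_path):
    path = tmp_path / "proteinGroups.txt"
    lines = ["\t".join(MAXQUANT_HEADER)] + ["\t".join(r) for r in MAXQUANT_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return str(path)
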