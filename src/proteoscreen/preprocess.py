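"""Reading and conditioning of quantitative proteomics matrices.

Covers the first stage of the screening workflow: parsing MaxQuant
``proteinGroups.txt`` or generic delimited matrices, removing features with
excessive missingness, global-minimum imputation, and between-sample
normalization (quantile, LOESS against a median reference, per-feature
standardization, or none).
"""

from __future__ import annotations

import csv
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrix import IntensityMatrix

__all__ = [
    "read_maxquant",
    "read_matrix",
    "filter_missing_features",
    "impute_minimum",
    "normalize",
    "write_matrix",
    "NORMALIZATION_METHODS",
]

NA_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}
NORMALIZATION_METHODS = ("quantile", "loess", "standardize", "none")

# MaxQuant decoy/contaminant flag columns; rows marked "+" are dropped.
_MAXQUANT_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


class MatrixFormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def _sniff_sep(path: str) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_maxquant(path: str, quant_column_prefix: str = "LFQ intensity") -> IntensityMatrix:
    """Read a MaxQuant ``proteinGroups.txt`` table into an :class:`IntensityMatrix`.

    Parameters
    ----------
    path
        Tab-separated proteinGroups file with a header row.
    quant_column_prefix
        Which quantification columns to take: ``"Intensity"``, ``"iBAQ"`` or
        ``"LFQ intensity"``.  Sample names are the header suffix after the
        prefix and one space.

    Notes
    -----
    Rows flagged ``+`` in the ``Reverse``, ``Potential contaminant`` or
    ``Only identified by site`` columns are dropped (decoys and artefacts).
    Zero intensities mean "not quantified" in MaxQuant output and are
    converted to missing entries.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         quoting=csv.QUOTE_NONE)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixFormatError(f"cannot parse {path!r} as tab-separated: {exc}") from exc
    if df.empty or df.shape[1] < 2:
        raise MatrixFormatError(f"{path!r}: no tab-separated header row found")

    prefix = quant_column_prefix.rstrip()
    quant_cols = [c for c in df.columns if c.startswith(prefix + " ")]
    # bare "Intensity" must not swallow "LFQ intensity <sample>" style columns
    if prefix == "Intensity":
        quant_cols = [c for c in quant_cols if c.split(" ", 1)[0] == "Intensity"]
    if not quant_cols:
        raise MatrixFormatError(
            f"no columns matching prefix {quant_column_prefix!r} in {path!r}"
        )
    sample_ids = [c[len(prefix) + 1:] for c in quant_cols]
    if len(set(sample_ids)) != len(sample_ids):
        raise MatrixFormatError(f"duplicate sample columns for prefix {quant_column_prefix!r}")

    keep = np.ones(len(df), dtype=bool)
    for flag_col in _MAXQUANT_FLAG_COLUMNS:
        if flag_col in df.columns:
            keep &= df[flag_col].str.strip() != "+"
    df = df.loc[keep]

    id_col = next(
        (c for c in ("Protein IDs", "Majority protein IDs", "id") if c in df.columns),
        None,
    )
    if id_col is not None:
        feature_ids = df[id_col].tolist()
    else:
        feature_ids = [f"feature_{i}" for i in range(len(df))]
    # protein groups can repeat ids after filtering weirdness; disambiguate
    if len(set(feature_ids)) != len(feature_ids):
        seen: dict[str, int] = {}
        uniq = []
        for fid in feature_ids:
            seen[fid] = seen.get(fid, 0) + 1
            uniq.append(fid if seen[fid] == 1 else f"{fid}.{seen[fid]}")
        feature_ids = uniq

    raw = df[quant_cols].to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in NA_TOKENS:
            values[i, j] = np.nan
            continue
        try:
            values[i, j] = float(cell)
        except ValueError as exc:
            raise MatrixFormatError(
                f"non-numeric value {cell!r} at row {feature_ids[i]!r}, "
                f"column {quant_cols[j]!r}"
            ) from exc
    mask = ~np.isfinite(values) | (values == 0)
    values[mask] = np.nan
    return IntensityMatrix(values, mask, feature_ids, sample_ids, log_transformed=False)


def read_matrix(path: str, orientation: str = "features_in_rows") -> IntensityMatrix:
    """Read a generic labelled numeric matrix (TSV or CSV).

    Empty cells and NA tokens ("NA", "NaN", ...) mark missing values.
    ``orientation="samples_in_rows"`` transposes the file on read so the
    result is always feature x sample.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        kind = "feature" if orientation == "samples_in_rows" else "sample"
        raise MatrixFormatError(f"duplicate {kind} labels in {path!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "samples_in_rows":
        df = df.T
    feature_ids = [str(x) for x in df.index]
    sample_ids = [str(x) for x in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise MatrixFormatError(f"duplicate sample labels in {path!r}")
    if len(set(feature_ids)) != len(feature_ids):
        raise MatrixFormatError(f"duplicate feature labels in {path!r}")

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in NA_TOKENS:
            values[i, j] = np.nan
            continue
        try:
            values[i, j] = float(cell)
        except ValueError as exc:
            raise MatrixFormatError(
                f"non-numeric cell {cell!r} at feature {feature_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            ) from exc
    mask = np.isnan(values)
    return IntensityMatrix(values, mask, feature_ids, sample_ids)


def write_matrix(m: IntensityMatrix, path: str) -> None:
    """Write features-in-rows TSV; missing entries become empty cells."""
    df = m.to_frame()
    df.to_csv(path, sep="\t", na_rep="", index_label="feature")


def filter_missing_features(
    m: IntensityMatrix, max_missing_frac: float = 0.75
) -> IntensityMatrix:
    """Drop features whose missing fraction strictly exceeds the threshold.

    Features missing in exactly ``max_missing_frac`` of samples are kept;
    only a strictly greater fraction removes them.  Sample set and the
    order of surviving features are unchanged.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.missing_mask.mean(axis=1)
    keep = frac <= max_missing_frac
    if not keep.any():
        warnings.warn("all features removed by missing-value filter", stacklevel=2)
    return m.subset_features(keep)


def impute_minimum(m: IntensityMatrix) -> IntensityMatrix:
    """Replace every missing entry with the global minimum observed value."""
    observed = m.observed_values()
    if observed.size == 0:
        raise ValueError("cannot impute an all-missing matrix")
    if not m.has_missing:
        return m.copy()
    fill = observed.min()
    values = np.where(m.missing_mask, fill, m.values)
    mask = np.zeros_like(m.missing_mask)
    return IntensityMatrix(values, mask, list(m.feature_ids), list(m.sample_ids),
                           m.log_transformed)


def normalize(m: IntensityMatrix, method: str = "quantile", *,
              loess_span: float = 0.7) -> IntensityMatrix:
    """Between-sample normalization of a complete (imputed) matrix.

    Methods
    -------
    quantile
        Each sample's k-th order statistic is replaced by the mean of the
        k-th order statistics across samples; ties within a sample receive
        the mean of their tied quantile means.
    loess
        Per sample, a locally weighted regression of the sample's log2
        values against the per-feature median reference profile is fitted
        and the fitted deviation from the reference removed.
    standardize
        Each feature rescaled to mean 0, unit variance across samples.
        Zero-variance features become all-zero with a warning.
    none
        Identity.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization method {method!r}; valid: {NORMALIZATION_METHODS}"
        )
    if method == "none":
        return m.copy()
    if m.has_missing:
        raise ValueError(f"normalize(method={method!r}) requires a complete matrix; impute first")

    X = m.values  # features x samples
    if method == "quantile":
        out = _quantile_normalize(X)
        return IntensityMatrix(out, np.zeros_like(m.missing_mask), list(m.feature_ids),
                               list(m.sample_ids), m.log_transformed)
    if method == "standardize":
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        const = (sd == 0).ravel()
        if const.any():
            warnings.warn(f"{const.sum()} zero-variance features set to zero under "
                          "standardize", stacklevel=2)
        sd_safe = np.where(sd == 0, 1.0, sd)
        out = (X - mean) / sd_safe
        out[const, :] = 0.0
        return IntensityMatrix(out, np.zeros_like(m.missing_mask), list(m.feature_ids),
                               list(m.sample_ids), m.log_transformed)
    # loess
    work = m if m.log_transformed else m.to_log2()
    if work.has_missing:  # log of imputed zeros cannot occur post impute_minimum
        raise ValueError("loess normalization needs strictly positive intensities")
    L = work.values
    ref = np.median(L, axis=1)
    out = np.empty_like(L)
    for j in range(L.shape[1]):
        fitted = sm.nonparametric.lowess(
            L[:, j], ref, frac=loess_span, it=1, return_sorted=False,
        )
        out[:, j] = L[:, j] - (fitted - ref)
    if not m.log_transformed:
        out = np.power(2.0, out)
    return IntensityMatrix(out, np.zeros_like(m.missing_mask), list(m.feature_ids),
                           list(m.sample_ids), m.log_transformed)


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Classic quantile normalization, features x samples, ties -> mean of means."""
    order = np.argsort(X, axis=0, kind="stable")
    ranks_sorted = np.take_along_axis(X, order, axis=0)
    target = ranks_sorted.mean(axis=1)  # mean of k-th order statistics
    out = np.empty_like(X)
    n = X.shape[0]
    positions = np.empty(n, dtype=int)
    for j in range(X.shape[1]):
        col = X[:, j]
        positions[order[:, j]] = np.arange(n)
        mapped = target[positions]
        # average target values over tied input values within the sample
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=mapped, minlength=uniq.size)
        counts = np.bincount(inv, minlength=uniq.size)
        out[:, j] = (sums / counts)[inv]
    return out


def preprocess_pipeline(
    m: IntensityMatrix,
    *,
    max_missing_frac: float = 0.75,
    method: str = "quantile",
) -> IntensityMatrix:
    """filter -> impute -> normalize, the default conditioning chain."""
    m = filter_missing_features(m, max_missing_frac)
    m = impute_minimum(m)
    return normalize(m, method)
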