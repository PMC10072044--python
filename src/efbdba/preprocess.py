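"""Cleaning and standardisation ahead of feature selection.

The pipeline order is fixed: duplicate-feature averaging, Tukey-fence
outlier flagging, KNN imputation of the resulting holes, then z-score
normalisation.  Outliers are *re-flagged as missing* (never edited in
place) so the same KNN fill handles both missingness sources.
"""

from __future__ import annotations

import logging

import numpy as np

from .dataio import BDBAConfig, ExpressionDataset, ValidationError

logger = logging.getLogger("efbdba")

__all__ = [
    "average_duplicate_features",
    "tukey_flag_outliers",
    "knn_impute",
    "zscore",
    "preprocess_pipeline",
]


def average_duplicate_features(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse features sharing an identifier to their per-sample mean.

    Missing entries are excluded from the mean; a cell that is missing in
    every duplicate stays missing.  First-occurrence order is preserved.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, fid in enumerate(ds.feature_ids):
        if fid not in groups:
            groups[fid] = []
            order.append(fid)
        groups[fid].append(j)
    if len(order) == ds.n_features:
        return ds.copy()

    out = np.empty((ds.n_samples, len(order)), dtype=float)
    for k, fid in enumerate(order):
        cols = ds.values[:, groups[fid]]
        with np.errstate(invalid="ignore"):
            counts = np.sum(~np.isnan(cols), axis=1)
            sums = np.nansum(cols, axis=1)
        out[:, k] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    logger.info(
        "averaged %d duplicate feature columns into %d unique features",
        ds.n_features - len(order),
        len(order),
    )
    return ExpressionDataset(out, ds.labels.copy(), order, list(ds.sample_ids), ds.class_names)


def tukey_flag_outliers(ds: ExpressionDataset, k: float = 1.5) -> ExpressionDataset:
    """Flag per-feature Tukey-fence outliers as missing.

    Values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` (quartiles with linear
    interpolation over non-missing values) become ``NaN``.  Features with
    fewer than 4 observed values are skipped.
    """
    if k <= 0:
        raise ValidationError("Tukey fence multiplier k must be > 0")
    out = ds.copy()
    n_flagged = 0
    for j in range(out.n_features):
        col = out.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 4:
            logger.debug("feature %s: <4 observed values, Tukey test skipped", out.feature_ids[j])
            continue
        q1, q3 = np.percentile(obs, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        with np.errstate(invalid="ignore"):
            bad = (col < lo) | (col > hi)
        n_flagged += int(bad.sum())
        col[bad] = np.nan
    if n_flagged:
        logger.info("Tukey test flagged %d outlier cells as missing", n_flagged)
    return out


def _sample_distances(values: np.ndarray, i: int) -> np.ndarray:
    """RMS distance from sample i to every sample over mutually observed features."""
    n = values.shape[0]
    obs_i = ~np.isnan(values[i])
    d = np.full(n, np.inf)
    for t in range(n):
        if t == i:
            continue
        shared = obs_i & ~np.isnan(values[t])
        m = int(shared.sum())
        if m == 0:
            continue
        diff = values[i, shared] - values[t, shared]
        d[t] = float(np.sqrt(np.mean(diff * diff)))
    return d


def knn_impute(ds: ExpressionDataset, k: int = 5) -> ExpressionDataset:
    """Fill missing cells from the k nearest samples.

    Each hole is filled with the mean of the feature's values over the
    ``k`` nearest samples (root-mean-square Euclidean distance on mutually
    observed features) that have the feature observed.  A single pass on
    the original values: fills never feed back into distances.
    """
    if k < 1:
        raise ValidationError("knn_impute requires k >= 1")
    missing = np.isnan(ds.values)
    if not missing.any():
        return ds.copy()
    if missing.all(axis=1).any():
        bad = [ds.sample_ids[i] for i in np.where(missing.all(axis=1))[0]]
        raise ValidationError(f"samples with all values missing: {bad}")
    if missing.all(axis=0).any():
        bad = [ds.feature_ids[j] for j in np.where(missing.all(axis=0))[0]]
        raise ValidationError(f"features with no observed value: {bad}")

    src = ds.values
    out = ds.copy()
    for i in np.where(missing.any(axis=1))[0]:
        d = _sample_distances(src, i)
        order = np.argsort(d, kind="stable")
        for j in np.where(missing[i])[0]:
            donors = [t for t in order if np.isfinite(d[t]) and not missing[t, j]]
            if not donors:
                raise ValidationError(
                    f"no donor sample for cell ({ds.sample_ids[i]}, {ds.feature_ids[j]})"
                )
            take = donors[:k]
            out.values[i, j] = float(np.mean(src[take, j]))
    return out


def zscore(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardise each feature to mean 0 and population SD 1.

    Zero-variance features become all-zeros (logged) rather than NaN.
    Requires a complete matrix.
    """
    if np.isnan(ds.values).any():
        raise ValidationError("zscore requires a matrix without missing cells")
    out = ds.copy()
    mu = out.values.mean(axis=0)
    sd = out.values.std(axis=0)  # population SD: scaling, not inference
    const = sd == 0
    if const.any():
        logger.info("%d constant features set to all-zeros by z-score", int(const.sum()))
    sd_safe = np.where(const, 1.0, sd)
    out.values = (out.values - mu) / sd_safe
    out.values[:, const] = 0.0
    return out


def preprocess_pipeline(
    ds: ExpressionDataset, cfg: BDBAConfig | None = None
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Run dedup -> Tukey -> KNN-impute -> z-score.

    Returns ``(standardised, imputed)``: the z-scored dataset consumed by
    feature selection, and the imputed pre-normalisation dataset on which
    fold changes and t statistics remain interpretable.
    """
    cfg = cfg or BDBAConfig()
    ds = average_duplicate_features(ds)
    ds = tukey_flag_outliers(ds, k=cfg.tukey_k)
    imputed = knn_impute(ds, k=cfg.knn_impute_k)
    return zscore(imputed), imputed
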