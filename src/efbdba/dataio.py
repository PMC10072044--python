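"""Expression-matrix I/O, run configuration and run artifacts.

The containers defined here are shared by every stage of the pipeline:

* :class:`ExpressionDataset` — a samples x features numeric matrix with
  binary class labels.  Missing entries are represented by ``NaN`` (never
  by 0, which is a legitimate expression value).
* :class:`BDBAConfig` — every tunable of the method, including the
  evolutionary-search parameters (max iterations ``G``, population size
  ``NP``, the vulture-phase probabilities ``P1``/``P2``, the adaptive
  crossover parameter ``alpha``, scaling-factor bounds) and the
  filter/preprocessing knobs.  All randomness in a run flows from the
  single seeded generator returned by :meth:`BDBAConfig.make_rng`.
* :class:`RunReport` — the artifact of a wrapper run: best mask, selected
  feature identifiers, per-generation fitness trace, classification
  metrics and per-feature biomarker statistics.

Expression matrices are read from delimited text (CSV/TSV).  The default
orientation has samples as rows, a header row of feature identifiers and
one label column; ``orientation="features_in_rows"`` reads the transposed
layout (features as rows, one label row).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("efbdba")

__all__ = [
    "ExpressionDataset",
    "BDBAConfig",
    "RunReport",
    "ParseError",
    "ValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_report",
    "read_report",
]


class ParseError(ValueError):
    """A delimited input file could not be parsed."""


class ValidationError(ValueError):
    """Inputs violate a structural precondition (shapes, classes, ids)."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A labelled expression matrix.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; ``NaN`` marks a missing cell.
    labels
        Per-sample binary class, 0 = negative, 1 = positive.
    feature_ids
        One identifier per feature (duplicates are only legal before the
        deduplication step of preprocessing).
    sample_ids
        One unique identifier per sample.
    class_names
        Original label strings as ``(negative, positive)``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    class_names: tuple[str, str] = ("neg", "pos")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValidationError(
                f"label/sample-id length mismatch: {len(self.labels)} labels, "
                f"{len(self.sample_ids)} sample ids, {n} rows"
            )
        if len(self.feature_ids) != p:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {p} feature columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids must be unique")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def require_two_classes(self) -> None:
        present = np.unique(self.labels)
        if len(present) != 2:
            raise ValidationError(
                f"exactly two classes required, found labels {present.tolist()}"
            )

    # -- views -------------------------------------------------------------

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(),
            self.labels.copy(),
            list(self.feature_ids),
            list(self.sample_ids),
            self.class_names,
        )

    def subset_features(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given feature indices (order kept)."""
        idx = list(indices)
        return ExpressionDataset(
            self.values[:, idx],
            self.labels.copy(),
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.class_names,
        )


@dataclass
class BDBAConfig:
    """All tunables of the two-stage method.

    Wrapper-stage parameters follow the published defaults: ``G=500``
    iterations, population ``NP=30``, vulture probabilities ``P1=0.6`` /
    ``P2=0.4``, adaptive crossover parameter ``alpha=0.9`` and scaling
    factor bounds ``f_min=0.1`` / ``f_max=0.9``.  Filter-stage and
    preprocessing knobs are package defaults documented in
    ``docs/methods.md``.
    """

    # wrapper stage
    G: int = 500
    NP: int = 30
    P1: float = 0.6
    P2: float = 0.4
    alpha: float = 0.9
    f_min: float = 0.1
    f_max: float = 0.9
    p_init: float = 0.5
    bavoa_enabled: bool = True
    bavoa_fraction: float = 0.4  # first fraction of iterations eligible for vulture moves
    rng_seed: int = 0

    # filter stage
    relevance_keep_fraction: float = 0.2  # keep the top fraction by r_cf
    relevance_threshold: float | None = None  # absolute delta overrides the quantile
    comp_draws: int = 20  # sample draws for the complementarity average
    smote_k: int = 5
    fisher_top_k: int = 100
    hetero_neighbor: str = "index"  # or "euclidean"
    shared_rand_per_dim: bool = False  # per-dimension rand in vulture moves

    # preprocessing
    tukey_k: float = 1.5
    knn_impute_k: int = 5

    # fitness / evaluation
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValidationError("G must be >= 1")
        if self.NP < 4:
            raise ValidationError("NP must be >= 4 (mutation needs 3 donors != target)")
        if not (0.0 <= self.f_min < self.f_max <= 1.0):
            raise ValidationError("require 0 <= f_min < f_max <= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError("alpha must be in (0, 1]")
        for name in ("P1", "P2", "p_init"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if not (0.0 < self.relevance_keep_fraction <= 1.0):
            raise ValidationError("relevance_keep_fraction must be in (0, 1]")
        if self.relevance_threshold is not None and not (
            0.0 <= self.relevance_threshold < 0.8
        ):
            raise ValidationError("relevance_threshold must be in [0, 0.8)")
        if self.hetero_neighbor not in ("index", "euclidean"):
            raise ValidationError("hetero_neighbor must be 'index' or 'euclidean'")

    def make_rng(self) -> np.random.Generator:
        """The single seeded generator all stochastic operations draw from."""
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BDBAConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass
class RunReport:
    """Artifact of one wrapper run plus downstream evaluation."""

    config: dict
    best_mask: list[int]
    best_feature_ids: list[str]
    per_generation_best_fitness: list[float]
    best_accuracy_trace: list[float]
    metrics: dict = field(default_factory=dict)
    biomarker_stats: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.best_feature_ids) != int(np.sum(self.best_mask)):
            raise ValidationError("best_feature_ids inconsistent with best_mask")

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "best_mask": [int(b) for b in self.best_mask],
            "best_feature_ids": list(self.best_feature_ids),
            "per_generation_best_fitness": [float(v) for v in self.per_generation_best_fitness],
            "best_accuracy_trace": [float(v) for v in self.best_accuracy_trace],
            "metrics": self.metrics,
            "biomarker_stats": self.biomarker_stats,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunReport":
        return cls(
            config=dict(d["config"]),
            best_mask=list(d["best_mask"]),
            best_feature_ids=list(d["best_feature_ids"]),
            per_generation_best_fitness=list(d["per_generation_best_fitness"]),
            best_accuracy_trace=list(d["best_accuracy_trace"]),
            metrics=dict(d.get("metrics", {})),
            biomarker_stats=list(d.get("biomarker_stats", [])),
        )


# --------------------------------------------------------------------------
# reading / writing matrices
# --------------------------------------------------------------------------

_NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_expression_matrix(
    path: str | os.PathLike,
    orientation: str = "features_in_columns",
    label: str = "label",
    label_map: Mapping[str, int] | None = None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a labelled expression matrix from delimited text.

    ``features_in_columns`` (default): rows are samples, the first column
    holds sample ids, remaining columns are features, one of which
    (``label``) carries the class label.  ``features_in_rows``: rows are
    features, columns are samples, and one row (index ``label``) carries
    the labels.

    Empty cells and the tokens NA/NaN/null (case-insensitive) become
    missing values.  Label values are mapped deterministically: the
    lexicographically first class is negative (0) unless ``label_map``
    (label string -> 0/1) overrides.
    """
    if orientation not in ("features_in_columns", "features_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = sep or _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if orientation == "features_in_rows":
        if label not in df.index:
            raise ParseError(f"{path}: label row {label!r} not found")
        df = df.T  # now rows = samples, columns = features (+ label)
    if label not in df.columns:
        raise ParseError(f"{path}: label column {label!r} not found")

    raw_labels = [str(v).strip() for v in df[label]]
    feat_df = df.drop(columns=[label])
    values = np.empty(feat_df.shape, dtype=float)
    cells = feat_df.to_numpy()
    for j, fid in enumerate(feat_df.columns):
        for i in range(cells.shape[0]):
            tok = str(cells[i, j]).strip()
            if tok.lower() in _NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except ValueError as exc:
                # +2: one header line, one for 0-based row index
                line = i + 2 if orientation == "features_in_columns" else j + 2
                raise ParseError(
                    f"{path}: line {line}: cannot parse {tok!r} "
                    f"(feature {fid!r}, sample {feat_df.index[i]!r})"
                ) from exc

    classes = sorted(set(raw_labels))
    if label_map is not None:
        mapping = dict(label_map)
        missing = set(raw_labels) - set(mapping)
        if missing:
            raise ValidationError(f"label_map misses classes {sorted(missing)}")
        neg = sorted(k for k, v in mapping.items() if v == 0)
        pos = sorted(k for k, v in mapping.items() if v == 1)
        names = (neg[0] if neg else "neg", pos[0] if pos else "pos")
    else:
        if len(classes) != 2:
            raise ValidationError(
                f"{path}: exactly two classes required, found {classes}"
            )
        mapping = {classes[0]: 0, classes[1]: 1}
        names = (classes[0], classes[1])
    labels = np.array([mapping[v] for v in raw_labels], dtype=np.int8)
    if len(np.unique(labels)) != 2:
        raise ValidationError(f"{path}: exactly two classes required")

    return ExpressionDataset(
        values=values,
        labels=labels,
        feature_ids=list(feat_df.columns),
        sample_ids=list(feat_df.index),
        class_names=names,
    )


def write_expression_matrix(
    ds: ExpressionDataset,
    path: str | os.PathLike,
    orientation: str = "features_in_columns",
    label: str = "label",
    sep: str | None = None,
) -> None:
    """Write a dataset back to delimited text (inverse of the reader)."""
    sep = sep or _sep_for(path)
    lab = [ds.class_names[v] for v in ds.labels]
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.feature_ids)
    df.insert(0, label, lab)
    if orientation == "features_in_rows":
        df = df.T
    elif orientation != "features_in_columns":
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep, float_format="%.12g", na_rep="NA")


# --------------------------------------------------------------------------
# run artifacts
# --------------------------------------------------------------------------


def _json_safe(obj):
    """Replace non-finite floats with None so JSON stays standard."""
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def write_report(report: RunReport, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the run artifacts.

    Produces ``selected_features.tsv`` (feature_id, t, p_value, FC, rank)
    and ``run_report.json`` (config echo, metrics, fitness trace, mask).
    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    tsv_path = os.path.join(out_dir, "selected_features.tsv")
    json_path = os.path.join(out_dir, "run_report.json")

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tt\tp_value\tFC\trank\n")
        stats = {s["feature_id"]: s for s in report.biomarker_stats}
        for fid in report.best_feature_ids:
            s = stats.get(fid, {})
            fc = s.get("FC")
            fc_txt = "NA" if fc is None or (isinstance(fc, float) and math.isnan(fc)) else f"{fc:.6g}"
            fh.write(
                f"{fid}\t{s.get('t', float('nan')):.6g}\t"
                f"{s.get('p_value', float('nan')):.6g}\t{fc_txt}\t{s.get('rank', 'NA')}\n"
            )

    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(_json_safe(report.to_dict()), fh, indent=1, sort_keys=True, allow_nan=False)
        fh.write("\n")
    logger.info("wrote report artifacts to %s", out_dir)
    return {"tsv": tsv_path, "json": json_path}


def read_report(json_path: str | os.PathLike) -> RunReport:
    """Re-read ``run_report.json``; field-equal to the written report."""
    with open(json_path, "r", encoding="utf-8") as fh:
        return RunReport.from_dict(json.load(fh))
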