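"""Synthetic microarray-like data with planted ground truth.

Emulates the regime the method targets — far more features than samples —
with four planted feature kinds:

* **informative**: class-shifted Gaussians, mean ``±effect_size/2`` by
  class, SD ``noise_sd``;
* **redundant**: near-copies of informative features (additive noise at
  one tenth of ``noise_sd``);
* **complementary pairs**: each feature individually class-symmetric (a
  ±a two-component mixture in both classes) but the *pair* separable —
  within class 0 the two components share their sign, within class 1
  they oppose, so only the joint sign pattern carries the label;
* **noise**: class-independent Gaussians.

Missing cells and Tukey-detectable outliers can be injected at given
rates.  The generator returns the dataset together with the ground-truth
index sets so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .dataio import ExpressionDataset, ValidationError, write_expression_matrix

__all__ = ["make_synthetic", "make_worked_toys"]


def make_synthetic(
    n_samples: int = 100,
    n_features: int = 1000,
    n_informative: int = 20,
    n_redundant: int = 10,
    n_complementary_pairs: int = 5,
    class_balance: float = 0.5,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    outlier_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionDataset, dict]:
    """Generate a labelled expression matrix with planted structure.

    Returns ``(dataset, truth)`` where ``truth`` maps the kinds
    ``informative`` / ``redundant`` / ``complementary`` (as index pairs) /
    ``noise`` to feature indices, plus ``redundant_source`` giving each
    redundant feature's informative origin.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    planted = n_informative + n_redundant + 2 * n_complementary_pairs
    if planted > n_features:
        raise ValidationError(
            f"planted features ({planted}) exceed n_features ({n_features})"
        )
    if n_samples < 10:
        raise ValidationError("need at least 10 samples")
    if n_redundant > 0 and n_informative == 0:
        raise ValidationError("redundant features need informative sources")

    n_pos = int(round(n_samples * class_balance))
    n_pos = min(max(n_pos, 2), n_samples - 2)
    y = np.zeros(n_samples, dtype=np.int8)
    y[:n_pos] = 1
    rng.shuffle(y)  # interleave classes in sample order

    X = np.empty((n_samples, n_features))
    col = 0
    shift = np.where(y == 1, effect_size / 2.0, -effect_size / 2.0)

    informative = list(range(col, col + n_informative))
    for _ in range(n_informative):
        X[:, col] = shift + rng.normal(0.0, noise_sd, n_samples)
        col += 1

    redundant = list(range(col, col + n_redundant))
    redundant_source = []
    for r in range(n_redundant):
        src = informative[r % max(n_informative, 1)]
        redundant_source.append(src)
        X[:, col] = X[:, src] + rng.normal(0.0, 0.1 * noise_sd, n_samples)
        col += 1

    complementary = []
    a = effect_size if effect_size > 0 else 1.0
    for _ in range(n_complementary_pairs):
        comp = rng.integers(0, 2, n_samples)  # latent mixture component
        s1 = np.where(comp == 1, a, -a)
        # class 0: signs agree; class 1: signs oppose
        s2 = np.where(y == 0, s1, -s1)
        X[:, col] = s1 + rng.normal(0.0, noise_sd, n_samples)
        X[:, col + 1] = s2 + rng.normal(0.0, noise_sd, n_samples)
        complementary.append([col, col + 1])
        col += 2

    noise = list(range(col, n_features))
    X[:, col:] = rng.normal(0.0, noise_sd, (n_samples, n_features - col))

    if outlier_rate > 0:
        cells = rng.random((n_samples, n_features)) < outlier_rate
        signs = rng.choice([-1.0, 1.0], size=(n_samples, n_features))
        spread = X.std(axis=0, keepdims=True) + 1.0
        X = np.where(cells, X.mean(axis=0, keepdims=True) + signs * 10.0 * spread, X)
    if missing_rate > 0:
        holes = rng.random((n_samples, n_features)) < missing_rate
        # keep every feature and sample at least partly observed
        holes[0, :] = False
        holes[:, 0] = False
        X[holes] = np.nan

    width = len(str(n_features))
    ds = ExpressionDataset(
        values=X,
        labels=y,
        feature_ids=[f"g{j:0{width}d}" for j in range(n_features)],
        sample_ids=[f"S{i:03d}" for i in range(n_samples)],
        class_names=("normal", "tumor"),
    )
    truth = {
        "informative": informative,
        "redundant": redundant,
        "redundant_source": redundant_source,
        "complementary": complementary,
        "noise": noise,
    }
    return ds, truth


def make_worked_toys(out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the small deterministic fixtures used in worked examples.

    All fixtures are synthetic, hand-specified values (no external data)
    and load through :func:`efbdba.dataio.read_expression_matrix`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    # oversampling toy: interpolation from (0,0) toward (2,-2) at t=0.5 -> (1,1)
    ds = ExpressionDataset(
        values=np.array([[0.0, 0.0], [2.0, -2.0], [0.5, 0.5], [1.0, 1.0]]),
        labels=np.array([0, 0, 1, 1]),
        feature_ids=["fA", "fB"],
        sample_ids=["s1", "s2", "s3", "s4"],
        class_names=("minor", "major"),
    )
    paths["smote"] = os.path.join(out_dir, "smote_toy.csv")
    write_expression_matrix(ds, paths["smote"])

    # complementarity toy: one sample per class, dis = |0-1| + |0-2| = 3
    ds = ExpressionDataset(
        values=np.array([[0.0, 0.0], [1.0, 2.0]]),
        labels=np.array([0, 1]),
        feature_ids=["fp", "fq"],
        sample_ids=["s1", "s2"],
    )
    paths["complementarity"] = os.path.join(out_dir, "complementarity_toy.csv")
    write_expression_matrix(ds, paths["complementarity"])

    # Fisher toy: perfectly separated feature and a constant feature
    ds = ExpressionDataset(
        values=np.array([[0.0, 7.0], [0.0, 7.0], [1.0, 7.0], [1.0, 7.0]]),
        labels=np.array([0, 0, 1, 1]),
        feature_ids=["sep", "flat"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )
    paths["fisher"] = os.path.join(out_dir, "fisher_toy.csv")
    write_expression_matrix(ds, paths["fisher"])

    # confusion-matrix toy: TP=3 FP=1 FN=1 TN=5 as a label/prediction table
    conf = {
        "y_true": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        "y_pred": [1, 1, 1, 0, 1, 0, 0, 0, 0, 0],
    }
    paths["confusion"] = os.path.join(out_dir, "confusion_toy.json")
    with open(paths["confusion"], "w", encoding="utf-8") as fh:
        json.dump(conf, fh, indent=1)
        fh.write("\n")
    return paths
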