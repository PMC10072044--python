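"""Stage-1 ensemble filter: improved FCBF intersected with Fisher top-k.

The improved fast correlation-based filter (FCBF) replaces symmetric
uncertainty with Pearson correlation so it applies to continuous
expression values.  Its three ingredients:

* **relevance** ``r_cf = 0.8 * (1 - r_pn)`` where ``r_pn`` is the absolute
  Pearson correlation between a feature's positive-class and
  negative-class value vectors (class sizes equalised by a SMOTE-style
  oversampler, each vector sorted ascending before pairing so the score
  is permutation-invariant within class);
* **redundancy** pruning by the approximate Markov blanket rule: once a
  salient feature is selected, any remaining candidate whose absolute
  Pearson correlation with it reaches the candidate's own relevance is
  eliminated;
* **complementarity**: among the features a salient feature eliminates in
  one round, the one with the greatest Manhattan-distance complementarity
  to it is kept in a complementary set.

The final candidate pool is the intersection of the FCBF selection with
the top-k features by Fisher score (between-class over within-class
variance); an empty intersection falls back to the union so the
downstream wrapper always receives a non-empty pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import BDBAConfig, ExpressionDataset, ValidationError

logger = logging.getLogger("efbdba")

__all__ = [
    "FilterResult",
    "pearson",
    "smote_balance",
    "class_relevance",
    "complementarity",
    "improved_fcbf",
    "fisher_score",
    "build_pool",
]

_FISHER_EPS = 1e-12
RELEVANCE_WEIGHT = 0.8  # guard factor of the relevance score


@dataclass
class FilterResult:
    """Everything the filter stage computed."""

    relevance: np.ndarray  # r_cf per feature, in [0, 0.8]
    fisher_scores: np.ndarray  # J per feature, >= 0
    fcbf_optimal: list[int]  # salient set O, in selection order
    fcbf_complementary: list[int]  # complementary set
    fcbf_selected: list[int] = field(default_factory=list)  # O followed by new Cset members
    fisher_topk: list[int] = field(default_factory=list)
    pool: list[int] = field(default_factory=list)
    used_fallback: bool = False


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 by convention when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"pearson needs equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("pearson needs length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt(np.sum(dx * dx) * np.sum(dy * dy))
    if denom == 0.0:
        return 0.0
    return float(np.sum(dx * dy) / denom)


def smote_balance(
    pos: np.ndarray,
    neg: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class until the two sets are equal-sized.

    Each synthetic sample interpolates from a random minority sample
    ``s_i`` toward one of its k nearest same-class neighbours ``s_j`` as
    ``s_i + rand(0,1) * |s_i - s_j|`` with an *elementwise absolute*
    difference — the method's published variant, deliberately kept
    instead of conventional SMOTE's signed difference.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if len(pos) == len(neg):
        return pos, neg
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    m = len(minority)
    if m < 2:
        raise ValidationError("SMOTE needs at least 2 minority samples")
    k_eff = min(k, m - 1)
    if k_eff < k:
        logger.info("SMOTE neighbour count clipped from %d to %d", k, k_eff)

    # pairwise distances inside the minority class
    diffs = minority[:, None, :] - minority[None, :, :]
    dist = np.sqrt(np.sum(diffs * diffs, axis=2))
    np.fill_diagonal(dist, np.inf)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]

    synth = []
    for _ in range(len(majority) - m):
        i = int(rng.integers(m))
        j = int(neighbours[i, int(rng.integers(k_eff))])
        gap = np.abs(minority[i] - minority[j])
        synth.append(minority[i] + rng.random() * gap)
    minority_out = np.vstack([minority] + [s[None, :] for s in synth])
    if len(pos) < len(neg):
        return minority_out, neg
    return pos, minority_out


def class_relevance(
    feature: np.ndarray,
    labels: np.ndarray,
    k_smote: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Relevance r_cf of one feature to the class label, in [0, 0.8].

    The feature's per-class value vectors are size-equalised (SMOTE-style
    oversampling of the minority class), sorted ascending, and correlated;
    ``r_cf = 0.8 * (1 - |r|)``.  High correlation of the two class
    profiles means low class information.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    f_pos = feature[labels == 1]
    f_neg = feature[labels == 0]
    if f_pos.size == 0 or f_neg.size == 0:
        raise ValidationError("class_relevance requires both classes present")
    if f_pos.size != f_neg.size:
        if min(f_pos.size, f_neg.size) < 2:
            # cannot interpolate from one sample: replicate it (logged)
            logger.info("minority class has a single sample; replicating for relevance")
            if f_pos.size < f_neg.size:
                f_pos = np.repeat(f_pos, f_neg.size)
            else:
                f_neg = np.repeat(f_neg, f_pos.size)
        else:
            p, n = smote_balance(f_pos[:, None], f_neg[:, None], k_smote, rng)
            f_pos, f_neg = p[:, 0], n[:, 0]
    r_pn = abs(pearson(np.sort(f_pos), np.sort(f_neg)))
    return RELEVANCE_WEIGHT * (1.0 - r_pn)


def _hetero_nearest(
    i: int,
    labels: np.ndarray,
    values: np.ndarray | None = None,
    mode: str = "index",
) -> int:
    """Opposite-class neighbour of sample i.

    ``index`` mode (default): the opposite-class sample with the smallest
    index distance, ties to the lower index.  ``euclidean`` mode: nearest
    by Euclidean distance over all features.
    """
    others = np.where(labels != labels[i])[0]
    if others.size == 0:
        raise ValidationError("no opposite-class sample available")
    if mode == "index":
        gaps = np.abs(others - i)
        return int(others[np.argmin(gaps)])  # argmin ties -> first -> lower index
    d = np.sqrt(np.sum((values[others] - values[i]) ** 2, axis=1))
    return int(others[np.argmin(d)])


def complementarity(
    fp: int,
    fq: int,
    ds: ExpressionDataset,
    n: int = 20,
    rng: np.random.Generator | None = None,
    mode: str = "index",
) -> float:
    """Complementarity of the feature pair (fp, fq).

    Averages, over ``n`` distinct randomly drawn samples, the Manhattan
    distance between the sample and its heterogeneous (opposite-class)
    nearest neighbour restricted to the two feature dimensions.  Feature
    pairs that are only jointly informative place opposite-class
    neighbours far apart in this 2-D projection.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if n < 1:
        raise ValidationError("complementarity needs n >= 1")
    ds.require_two_classes()
    n_eff = min(n, ds.n_samples)
    if n_eff < n:
        logger.info("complementarity draw count clipped from %d to %d", n, n_eff)
    draws = rng.choice(ds.n_samples, size=n_eff, replace=False)
    total = 0.0
    for i in draws:
        j = _hetero_nearest(int(i), ds.labels, ds.values, mode)
        total += abs(ds.values[i, fp] - ds.values[j, fp]) + abs(
            ds.values[i, fq] - ds.values[j, fq]
        )
    return total / n_eff


def improved_fcbf(
    ds: ExpressionDataset,
    delta: float,
    rng: np.random.Generator,
    relevance: np.ndarray | None = None,
    n_comp: int = 20,
    smote_k: int = 5,
    hetero_mode: str = "index",
) -> tuple[list[int], list[int]]:
    """Relevance / redundancy / complementarity selection.

    Candidates are features with ``r_cf > delta`` ordered by decreasing
    relevance.  Repeatedly: promote the most relevant candidate to the
    optimal set ``O``; eliminate every remaining candidate whose absolute
    correlation with it reaches that candidate's own relevance
    (approximate Markov blanket); among the features eliminated in the
    round, keep the one most complementary to the salient feature.

    Returns ``(O, Cset)`` as original feature indices.
    """
    if not (0.0 <= delta < RELEVANCE_WEIGHT):
        raise ValidationError("delta must be in [0, 0.8)")
    if relevance is None:
        relevance = np.array(
            [class_relevance(ds.values[:, j], ds.labels, smote_k, rng) for j in range(ds.n_features)]
        )
    candidates = [j for j in range(ds.n_features) if relevance[j] > delta]
    if not candidates:
        logger.warning("improved FCBF: no feature exceeds the relevance threshold")
        return [], []
    # sort by relevance descending, stable (ties -> lower index)
    candidates.sort(key=lambda j: (-relevance[j], j))

    optimal: list[int] = []
    comp_set: list[int] = []
    remaining = list(candidates)
    while remaining:
        f_s = remaining.pop(0)
        optimal.append(f_s)
        kept, removed = [], []
        for f_j in remaining:
            r = abs(pearson(ds.values[:, f_s], ds.values[:, f_j]))
            (removed if r >= relevance[f_j] else kept).append(f_j)
        remaining = kept
        if removed:
            comps = [complementarity(f_s, f_j, ds, n_comp, rng, hetero_mode) for f_j in removed]
            best = removed[int(np.argmax(comps))]
            if best not in comp_set:
                comp_set.append(best)
    return optimal, comp_set


def fisher_score(ds: ExpressionDataset) -> np.ndarray:
    """Fisher score per feature: between-class over within-class variance.

    ``S_B = sum_i (n_i/n)(m_i - m)^2`` and
    ``S_w = (1/n) sum_i sum_{y in class i} (y - m_i)^2``;
    a vanishing within-class variance is regularised with a 1e-12 floor.
    """
    ds.require_two_classes()
    y = ds.labels
    n = ds.n_samples
    m_all = ds.values.mean(axis=0)
    s_b = np.zeros(ds.n_features)
    s_w = np.zeros(ds.n_features)
    for c in np.unique(y):
        block = ds.values[y == c]
        n_c = block.shape[0]
        m_c = block.mean(axis=0)
        s_b += (n_c / n) * (m_c - m_all) ** 2
        s_w += np.sum((block - m_c) ** 2, axis=0) / n
    return s_b / (s_w + _FISHER_EPS)


def build_pool(
    ds: ExpressionDataset,
    cfg: BDBAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FilterResult:
    """Run the full ensemble filter and return the candidate pool.

    The pool is ``fcbf_selected ∩ fisher_topk`` (preserving FCBF order);
    if empty, it falls back to the union (warned) so the wrapper stage
    always has features to search over.
    """
    cfg = cfg or BDBAConfig()
    rng = rng if rng is not None else cfg.make_rng()
    ds.require_two_classes()

    relevance = np.array(
        [class_relevance(ds.values[:, j], ds.labels, cfg.smote_k, rng) for j in range(ds.n_features)]
    )
    if cfg.relevance_threshold is not None:
        delta = cfg.relevance_threshold
    else:
        delta = float(np.quantile(relevance, 1.0 - cfg.relevance_keep_fraction))
        delta = min(delta, np.nextafter(RELEVANCE_WEIGHT, 0.0))
    optimal, comp_set = improved_fcbf(
        ds,
        delta,
        rng,
        relevance=relevance,
        n_comp=cfg.comp_draws,
        smote_k=cfg.smote_k,
        hetero_mode=cfg.hetero_neighbor,
    )
    fcbf_selected = optimal + [c for c in comp_set if c not in optimal]

    fisher = fisher_score(ds)
    k = min(cfg.fisher_top_k, ds.n_features)
    order = sorted(range(ds.n_features), key=lambda j: (-fisher[j], j))
    fisher_topk = order[:k]
    topk_set = set(fisher_topk)

    pool = [j for j in fcbf_selected if j in topk_set]
    used_fallback = False
    if not pool:
        used_fallback = True
        logger.warning(
            "ensemble filter: empty intersection of FCBF (%d) and Fisher top-%d; using the union",
            len(fcbf_selected),
            k,
        )
        pool = fcbf_selected + [j for j in fisher_topk if j not in set(fcbf_selected)]

    logger.info(
        "ensemble filter pool: %d features (FCBF %d, Fisher top-%d, fallback=%s)",
        len(pool),
        len(fcbf_selected),
        k,
        used_fallback,
    )
    return FilterResult(
        relevance=relevance,
        fisher_scores=fisher,
        fcbf_optimal=optimal,
        fcbf_complementary=comp_set,
        fcbf_selected=fcbf_selected,
        fisher_topk=fisher_topk,
        pool=pool,
        used_fallback=used_fallback,
    )
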