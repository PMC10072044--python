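"""Hybrid wrapper search (BDBA): binary DE fused with binary vultures.

One run evolves ``NP`` masks over the candidate pool for ``G``
generations.  During the first ``bavoa_fraction`` (default 40%) of the
iterations each individual draws a starvation rate; when ``|SR| < 1`` it
takes a binary-vultures move (exploration toward/away from the leader or
a transition move, binarized through the shifted sigmoid), otherwise —
and always in the remaining 60% — a plain IBDE step
(mutation -> crossover -> greedy selection).  Vulture children compete
with their parents through the same greedy selection rather than
replacing them unconditionally, which protects good masks from the
sparsity-inducing binarization.

The global best is archived separately from the population, ranked
lexicographically by (higher CV accuracy, fewer features, first found):
the beta-weighted fitness is time-varying, so raw fitness values are not
comparable across generations, but the archived accuracy trace is
monotone by construction.

RNG draw order (relied upon by regression oracles): per IBDE step —
donor indices, mutation uniforms (one block), jrand, crossover uniforms
(one block), optional repair bit; per vulture step — SR (3 draws),
branch uniform(s), move-specific draws, binarization uniforms, optional
repair bit.  The per-generation leader is derived before the individual
loop: opposition positions then the leader-choice uniform.
"""

from __future__ import annotations

import logging

import numpy as np

from . import bavoa as bv
from . import ibde
from .dataio import BDBAConfig, ExpressionDataset, RunReport, ValidationError
from .evaluate import FitnessEvaluator, biomarker_table, cv_metrics

logger = logging.getLogger("efbdba")

__all__ = ["init_population", "evolve", "final_subset", "run_pipeline"]


def init_population(
    L: int,
    NP: int,
    rng: np.random.Generator,
    p_init: float = 0.5,
) -> list[ibde.Individual]:
    """NP random masks with Bernoulli(p_init) bits; all-zero masks repaired."""
    if NP < 4 or L < 1:
        raise ValidationError("require NP >= 4 and L >= 1")
    masks = (rng.random((NP, L)) < p_init).astype(np.uint8)
    pop = []
    for row in masks:
        ibde.repair_mask(row, rng)
        pop.append(ibde.Individual(mask=row))
    return pop


class _Archive:
    """Elitist global best: higher accuracy, then fewer features, then first found."""

    def __init__(self) -> None:
        self.acc = -1.0
        self.num = 0
        self.mask: np.ndarray | None = None

    def offer(self, mask: np.ndarray, acc: float) -> None:
        num = int(mask.sum())
        if acc > self.acc or (acc == self.acc and num < self.num):
            self.acc, self.num, self.mask = acc, num, mask.copy()


def _ibde_step(
    i: int,
    pop: list[ibde.Individual],
    F: float,
    CR: float,
    rng: np.random.Generator,
) -> np.ndarray:
    others = [j for j in range(len(pop)) if j != i]
    r1, r2, r3 = rng.choice(others, size=3, replace=False)
    u = ibde.mutation(pop[r1].mask, pop[r2].mask, pop[r3].mask, F, rng)
    v = ibde.crossover(pop[i].mask, u, CR, rng)
    return ibde.repair_mask(v, rng)


def _bavoa_step(
    i: int,
    pop: list[ibde.Individual],
    x_best: np.ndarray,
    SR: float,
    cfg: BDBAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    x = pop[i].mask
    per_dim = cfg.shared_rand_per_dim
    if abs(SR) >= 0.5:  # exploration phase
        if rng.random() < cfg.P1:
            cont = bv.explore_toward_best(x, x_best, SR, rng, per_dim)
        else:
            others = [j for j in range(len(pop)) if j != i]
            r1, r2 = rng.choice(others, size=2, replace=False)
            cont = bv.explore_random(x, pop[r1].mask, pop[r2].mask, SR, rng, per_dim)
    else:  # transition phase
        cont = bv.transition_update(x, x_best, SR, cfg.P2, rng, per_dim)
    child = bv.binarize(cont, rng)
    return ibde.repair_mask(child, rng)


def evolve(
    ds_pool: ExpressionDataset,
    cfg: BDBAConfig | None = None,
    rng: np.random.Generator | None = None,
    evaluator: FitnessEvaluator | None = None,
) -> RunReport:
    """Run the hybrid search over the candidate pool and report the best subset."""
    cfg = cfg or BDBAConfig()
    rng = rng if rng is not None else cfg.make_rng()
    L = ds_pool.n_features
    if L < 1:
        raise ValidationError("candidate pool is empty")
    evaluator = evaluator or FitnessEvaluator(ds_pool, cfg)

    archive = _Archive()
    pop = init_population(L, cfg.NP, rng, cfg.p_init)
    for ind in pop:
        ind.cached_acc = evaluator.accuracy(ind.mask)
        archive.offer(ind.mask, ind.cached_acc)

    fitness_trace: list[float] = []
    acc_trace: list[float] = []

    for g in range(1, cfg.G + 1):
        beta = ibde.beta_weight(g, cfg.G)
        F = ibde.scaling_factor(g, cfg.G, cfg.f_min, cfg.f_max)
        CR = ibde.crossover_factor(g, cfg.G, cfg.alpha)
        vulture_phase = cfg.bavoa_enabled and (g / cfg.G) < cfg.bavoa_fraction

        x_best = None
        if vulture_phase:
            fits = [ibde.fitness(p.cached_acc, p.num, L, beta) for p in pop]
            leader = int(np.argmax(fits))  # ties -> lowest index
            x_first = pop[leader].mask
            x_new = bv.random_opposition(x_first, rng)
            x_best = bv.select_best_vulture(x_first, x_new, fits[leader], rng)

        for i in range(cfg.NP):
            if vulture_phase:
                SR = bv.starvation_rate(g, cfg.G, rng)
                if abs(SR) < 1.0:
                    child_mask = _bavoa_step(i, pop, x_best, SR, cfg, rng)
                else:
                    child_mask = _ibde_step(i, pop, F, CR, rng)
            else:
                child_mask = _ibde_step(i, pop, F, CR, rng)
            try:
                child = ibde.Individual(mask=child_mask)
                child.cached_acc = evaluator.accuracy(child.mask)
            except Exception:  # keep the parent on evaluation failure
                logger.exception("evaluation failed for individual %d at generation %d", i, g)
                continue
            archive.offer(child.mask, child.cached_acc)
            pop[i] = ibde.select(pop[i], child, beta, L)

        gen_best = max(ibde.fitness(p.cached_acc, p.num, L, beta) for p in pop)
        fitness_trace.append(float(gen_best))
        acc_trace.append(float(archive.acc))
        logger.info(
            "generation %d/%d: best fitness %.4f, archived acc %.4f (%d features)",
            g, cfg.G, gen_best, archive.acc, archive.num,
        )

    best_mask = archive.mask
    best_ids = [ds_pool.feature_ids[j] for j in np.where(best_mask == 1)[0]]
    return RunReport(
        config=cfg.to_dict(),
        best_mask=[int(b) for b in best_mask],
        best_feature_ids=best_ids,
        per_generation_best_fitness=fitness_trace,
        best_accuracy_trace=acc_trace,
    )


def final_subset(report: RunReport) -> list[str]:
    """Feature identifiers of the archived global-best mask."""
    return list(report.best_feature_ids)


def run_pipeline(
    ds: ExpressionDataset, cfg: BDBAConfig | None = None
) -> tuple[RunReport, "FilterResult"]:
    """Full pipeline: preprocess -> ensemble filter -> hybrid search -> evaluation.

    Returns the completed :class:`RunReport` (metrics and biomarker
    statistics filled in) and the stage-1 :class:`FilterResult`.
    Biomarker t/p/FC are computed on the imputed, pre-normalisation
    matrix so fold changes keep their meaning.
    """
    from .ensemble_filter import FilterResult, build_pool  # local: avoid import cycle
    from .preprocess import preprocess_pipeline

    cfg = cfg or BDBAConfig()
    rng = cfg.make_rng()
    clean, imputed = preprocess_pipeline(ds, cfg)
    fr = build_pool(clean, cfg, rng)
    ds_pool = clean.subset_features(fr.pool)
    report = evolve(ds_pool, cfg, rng)

    sel_pool_idx = [j for j, b in enumerate(report.best_mask) if b]
    sel_orig_idx = [fr.pool[j] for j in sel_pool_idx]
    report.metrics = cv_metrics(clean.subset_features(sel_orig_idx), cfg)
    report.biomarker_stats = biomarker_table(imputed, sel_orig_idx)
    return report, fr
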