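"""Improved binary differential evolution (IBDE) operators.

A binary DE tailored to feature selection: the mutation operator is
sparsity-inducing (a trial bit can only switch on where a random donor
already has it on, with probability tanh(F * donor-difference)), the
crossover factor CR decays over generations from alpha toward
0.2384*alpha, and the fitness trades cross-validated accuracy against
subset size with a weight beta that steps up every 100 generations —
ending in a pure-accuracy regime once beta reaches 0.9.

All operators are pure functions of masks, schedule values and a seeded
generator; population orchestration lives in :mod:`efbdba.bdba`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataio import ValidationError

__all__ = [
    "Individual",
    "scaling_factor",
    "mutation",
    "crossover_factor",
    "crossover",
    "beta_weight",
    "fitness",
    "select",
    "repair_mask",
]


@dataclass
class Individual:
    """A binary inclusion mask over the candidate pool with cached accuracy."""

    mask: np.ndarray
    cached_acc: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValidationError("mask entries must be 0/1")

    @property
    def num(self) -> int:
        return int(self.mask.sum())


def scaling_factor(g: int, G: int, f_min: float = 0.1, f_max: float = 0.9) -> float:
    """Inertial adaptive scaling factor, strictly decreasing in g.

    ``F = f_min + ((G - g + 1)/G) * (f_max - f_min)``, clamped to
    ``[f_min, f_max]``.  The printed source form divides by ``g``, which
    explodes above 1 early on and contradicts the stated requirement
    F in [0, 1]; the divisor is therefore G (see README).
    """
    if not (1 <= g <= G):
        raise ValidationError("require 1 <= g <= G")
    F = f_min + ((G - g + 1) / G) * (f_max - f_min)
    return min(max(F, f_min), f_max)


def mutation(
    x_r1: np.ndarray,
    x_r2: np.ndarray,
    x_r3: np.ndarray,
    F: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sparsity-inducing binary mutation.

    Per dimension j: ``diff_j = 0`` where the first two donors agree,
    else ``F * x_r1_j``; the bit turns on iff
    ``tanh(diff_j) >= rand(0,1)`` *and* the third donor has it on.
    Hence ``support(u) ⊆ support(x_r3)`` always, and the expected number
    of set bits is bounded by ``popcount(x_r3) * tanh(F)``.
    """
    x_r1 = np.asarray(x_r1, dtype=np.uint8)
    x_r2 = np.asarray(x_r2, dtype=np.uint8)
    x_r3 = np.asarray(x_r3, dtype=np.uint8)
    diff = np.where(x_r1 == x_r2, 0.0, F * x_r1.astype(float))
    pr = np.tanh(diff)
    u = (pr >= rng.random(len(x_r1))) & (x_r3 == 1)
    return u.astype(np.uint8)


def crossover_factor(g: int, G: int, alpha: float) -> float:
    """Adaptive crossover factor, monotone decreasing from ~alpha.

    ``CR = alpha * 2 e^{-(g/G)} / (e^{g/G} + e^{-(g/G)})``; at g=G this is
    0.2384*alpha (0.23 for alpha=1 after truncation).
    """
    if g < 0 or G < 1:
        raise ValidationError("require g >= 0 and G >= 1")
    t = g / G
    return alpha * 2.0 * math.exp(-t) / (math.exp(t) + math.exp(-t))


def crossover(
    x: np.ndarray,
    u: np.ndarray,
    CR: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover with one guaranteed trial coordinate (jrand)."""
    x = np.asarray(x, dtype=np.uint8)
    u = np.asarray(u, dtype=np.uint8)
    if x.shape != u.shape:
        raise ValidationError("crossover needs equal-length vectors")
    jrand = int(rng.integers(len(x)))
    take = rng.random(len(x)) <= CR
    take[jrand] = True
    return np.where(take, u, x).astype(np.uint8)


def beta_weight(g: int, G: int) -> float:
    """Segmented fitness weight: steps up by 100-generation blocks.

    ``beta = (floor(g/100) * 100) / G + 0.1``; for G=500 this is
    0.1/0.3/0.5/0.7/0.9 over successive blocks, and once beta reaches 0.9
    the fitness drops the size penalty entirely.
    """
    if g < 0:
        raise ValidationError("generation index must be >= 0")
    return (math.floor(g / 100) * 100) / G + 0.1


def fitness(acc: float, num: int, L: int, beta: float) -> float:
    """Segmented adaptive fitness.

    ``f = acc - beta * num / L`` while ``beta < 0.9``; from beta >= 0.9 the
    subset-size penalty is dropped and ``f = acc``.  An empty mask is a
    repair sentinel and scores -1.
    """
    if L < 1:
        raise ValidationError("pool size L must be >= 1")
    if num == 0:
        return -1.0
    if beta < 0.9:
        return acc - beta * (num / L)
    return acc


def select(x: Individual, v: Individual, beta: float, L: int) -> Individual:
    """Greedy selection at a common beta; ties keep the incumbent x."""
    fx = fitness(x.cached_acc, x.num, L, beta)
    fv = fitness(v.cached_acc, v.num, L, beta)
    return v if fv > fx else x


def repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Set one uniformly random bit if the mask is all-zero (in place)."""
    if mask.sum() == 0:
        mask[int(rng.integers(len(mask)))] = 1
    return mask
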