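"""Binary African vultures optimization (BAVOA) operators.

The African vultures optimizer drives individuals either to roam (random
exploration) or to track the current best individual, gated by a
time-decaying randomized starvation rate SR.  This binary variant keeps
the exploration and transition phases only, picks its leader by random
opposition-based learning (flip half of the best mask's bits, then choose
between original and opposite with the best's fitness as the keep
probability), and maps continuous position updates back to masks through
a shifted sigmoid with a random threshold.

Note the binarization inequality is ``rand > s``: a *larger* sigmoid
value gives a *lower* probability of selecting the bit.  This inversion
of the usual transfer-function convention is kept deliberately — it is
the published form and acts as a sparsity pressure (see README).
"""

from __future__ import annotations

import math

import numpy as np

from .dataio import ValidationError

__all__ = [
    "random_opposition",
    "select_best_vulture",
    "starvation_rate",
    "explore_random",
    "explore_toward_best",
    "transition_update",
    "binarize",
]

_SR_W = 2.5  # exponent of the sine term in the satiety decay


def random_opposition(x_first: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip exactly floor(L/2) uniformly chosen distinct bits."""
    x_first = np.asarray(x_first, dtype=np.uint8)
    L = len(x_first)
    if L < 2:
        raise ValidationError("random opposition needs dimension >= 2")
    pos = rng.choice(L, size=L // 2, replace=False)
    out = x_first.copy()
    out[pos] ^= 1
    return out


def select_best_vulture(
    x_first: np.ndarray,
    x_new: np.ndarray,
    f_first: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choose the leader: keep x_first with probability clamp(f_first, 0, 1)."""
    p = min(max(f_first, 0.0), 1.0)
    return x_first if rng.random() <= p else x_new


def starvation_rate(g: int, G: int, rng: np.random.Generator) -> float:
    """Signed starvation (satiety) rate, decaying to 0 at g = G.

    ``SR = (2*rand + 1) * z * (1 - g/G) + t`` with ``z ~ U(-1, 1)`` and
    ``t = h * (sin^w((pi/2)(g/G)) + cos((pi/2)(g/G)) - 1)``,
    ``h ~ U(-2, 2)``, ``w = 2.5``.  Callers branch on |SR|.
    """
    if not (1 <= g <= G):
        raise ValidationError("require 1 <= g <= G")
    rand = rng.random()
    z = rng.uniform(-1.0, 1.0)
    h = rng.uniform(-2.0, 2.0)
    frac = g / G
    t = h * (math.sin(math.pi / 2 * frac) ** _SR_W + math.cos(math.pi / 2 * frac) - 1.0)
    return (2.0 * rand + 1.0) * z * (1.0 - frac) + t


def _rand(rng: np.random.Generator, L: int, per_dim: bool):
    return rng.random(L) if per_dim else rng.random()


def explore_random(
    x: np.ndarray,
    x_r1: np.ndarray,
    x_r2: np.ndarray,
    SR: float,
    rng: np.random.Generator,
    per_dim: bool = False,
) -> np.ndarray:
    """Random roaming: ``x + D * SR`` with ``D = 2*rand*x_r1 - x_r2``.

    One shared rand per call by default, matching the scalar notation of
    the update rule; ``per_dim=True`` draws one per dimension.
    """
    x = np.asarray(x, dtype=float)
    x_r1 = np.asarray(x_r1, dtype=float)
    x_r2 = np.asarray(x_r2, dtype=float)
    if not (x.shape == x_r1.shape == x_r2.shape):
        raise ValidationError("explore_random needs equal-length vectors")
    D = 2.0 * _rand(rng, len(x), per_dim) * x_r1 - x_r2
    return x + D * SR


def explore_toward_best(
    x: np.ndarray,
    x_best: np.ndarray,
    SR: float,
    rng: np.random.Generator,
    per_dim: bool = False,
) -> np.ndarray:
    """Approach the leader at a random distance:
    ``x' = x_best - |2*rand*x_best - x| * SR``."""
    x = np.asarray(x, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    if x.shape != x_best.shape:
        raise ValidationError("explore_toward_best needs equal-length vectors")
    D = np.abs(2.0 * _rand(rng, len(x), per_dim) * x_best - x)
    return x_best - D * SR


def transition_update(
    x: np.ndarray,
    x_best: np.ndarray,
    SR: float,
    P2: float,
    rng: np.random.Generator,
    per_dim: bool = False,
) -> np.ndarray:
    """Transition-phase move: siege fight with probability P2, else a
    rotating flight around the leader.

    Siege: ``x' = D*(SR + rand) - (x_best - x)`` with
    ``D = |2*rand*x_best - x|``.  Rotating flight:
    ``x' = x_best - (S1 + S2)`` with
    ``S1 = x_best * (rand * x / (2 pi)) * cos(x)`` and
    ``S2 = x_best * (rand * x / (2 pi)) * sin(x)`` (elementwise, one rand
    drawn for each term).
    """
    x = np.asarray(x, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    if x.shape != x_best.shape:
        raise ValidationError("transition_update needs equal-length vectors")
    if rng.random() < P2:
        D = np.abs(2.0 * _rand(rng, len(x), per_dim) * x_best - x)
        return D * (SR + rng.random()) - (x_best - x)
    r5 = _rand(rng, len(x), per_dim)
    r6 = _rand(rng, len(x), per_dim)
    s1 = x_best * (r5 * x / (2.0 * math.pi)) * np.cos(x)
    s2 = x_best * (r6 * x / (2.0 * math.pi)) * np.sin(x)
    return x_best - (s1 + s2)


def binarize(x_cont: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shifted-sigmoid stochastic binarization.

    ``s_j = 1 / (1 + e^{-x_j - 2})`` and the bit is 1 iff ``rand > s_j``,
    i.e. ``P(bit = 1) = 1 - s_j``.  The shift by +2 biases bits off for
    positions near zero; the inverted inequality is intentional (see
    module docstring).
    """
    x_cont = np.asarray(x_cont, dtype=float)
    if not np.isfinite(x_cont).all():
        raise ValidationError("binarize requires finite entries")
    s = 1.0 / (1.0 + np.exp(-x_cont - 2.0))
    return (rng.random(len(x_cont)) > s).astype(np.uint8)
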