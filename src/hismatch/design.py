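"""Space-filling experimental designs and NROY "cloud" resampling.

Latin hypercube samples provide the simulation designs (points actually run
through the simulator); unscrambled Sobol' sequences provide the large
candidate sets used to probe and characterize the not-ruled-out-yet (NROY)
region.  The cloud technique repopulates a shrinking NROY region by
perturbing surviving points with multivariate normal noise of expanding
scale, so the boundary between plausible and implausible space is explored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import qmc

__all__ = [
    "SamplerConfig",
    "latin_hypercube",
    "sobol_points",
    "cloud_sample",
    "select_batch",
    "EmptyNROYError",
]


class EmptyNROYError(RuntimeError):
    """Raised when an operation needs NROY points but none survive."""


@dataclass
class SamplerConfig:
    """Settings for the cloud resampler.

    cloud_scale is the base SD of the multinormal perturbation in unit-cube
    units; each escalation round multiplies it by the round index, widening
    the search when acceptance is low.
    """

    seed: int = 0
    sobol_skip: int = 0
    cloud_scale: float = 0.05
    cloud_offspring: int = 5
    max_rounds: int = 50

    def __post_init__(self) -> None:
        if self.cloud_scale <= 0:
            raise ValueError("cloud_scale must be positive")
        if self.cloud_offspring < 1:
            raise ValueError("cloud_offspring must be >= 1")


def latin_hypercube(d: int, n: int, seed: int) -> np.ndarray:
    """n-point Latin hypercube in [0,1]^d: one point per column stratum."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    return sampler.random(n)


def sobol_points(d: int, n: int, skip: int = 0) -> np.ndarray:
    """First ``n`` points of the unscrambled d-dim Sobol' sequence after ``skip``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if skip < 0:
        raise ValueError("skip must be >= 0")
    with warnings.catch_warnings():
        # balance warning for n not a power of two is irrelevant here
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=d, scramble=False)
        if skip:
            sampler.fast_forward(skip)
        return sampler.random(n)


def cloud_sample(
    parents: np.ndarray,
    target_n: int,
    membership: Callable[[np.ndarray], np.ndarray],
    cfg: SamplerConfig,
) -> np.ndarray:
    """Repopulate a region by normal perturbation of its member points.

    Each round cycles through the parents, drawing ``cloud_offspring``
    children per parent from ``N(parent, (r * cloud_scale)^2 I)`` where
    ``r`` is the round index (the expanding scale).  Children outside the
    unit cube are rejected, then filtered by the ``membership`` predicate
    (vectorized: takes an ``m x d`` array, returns a boolean ``m``-vector).
    Stops when ``target_n`` accepted points exist or ``cfg.max_rounds`` is
    hit; in the latter case returns fewer points and emits a warning.
    """
    parents = np.atleast_2d(np.asarray(parents, dtype=float))
    if parents.shape[0] == 0:
        raise EmptyNROYError("cloud_sample needs at least one parent point")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")

    rng = np.random.default_rng(cfg.seed)
    d = parents.shape[1]
    accepted: list[np.ndarray] = []
    n_acc = 0
    per_pass = parents.shape[0] * cfg.cloud_offspring
    for round_idx in range(1, cfg.max_rounds + 1):
        scale = cfg.cloud_scale * round_idx
        # replicate the parent sweep enough times to plausibly fill the quota
        reps = max(1, -(-(target_n - n_acc) // per_pass))
        z = rng.standard_normal((reps * parents.shape[0], cfg.cloud_offspring, d))
        children = (np.tile(parents, (reps, 1))[:, None, :] + scale * z).reshape(-1, d)
        inside = np.all((children >= 0.0) & (children <= 1.0), axis=1)
        children = children[inside]
        if children.shape[0]:
            keep = np.asarray(membership(children), dtype=bool)
            children = children[keep]
        if children.shape[0]:
            accepted.append(children)
            n_acc += children.shape[0]
        if n_acc >= target_n:
            break
    else:
        warnings.warn(
            f"cloud_sample reached its round cap with {n_acc}/{target_n} points",
            RuntimeWarning,
            stacklevel=2,
        )
    if not accepted:
        return np.empty((0, d))
    out = np.vstack(accepted)
    return out[:target_n]


def select_batch(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Greedy maximin (farthest-point) subset of ``k`` rows.

    Starts from a seed-chosen row and repeatedly adds the point farthest
    (in Euclidean distance) from the already-selected set, keeping the batch
    space-filling inside the region the rows were drawn from.  Returns all
    rows when ``k >= n``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    n = pts.shape[0]
    if n == 0:
        raise EmptyNROYError("select_batch needs at least one point")
    if k >= n:
        return pts.copy()
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    mind = cdist(pts, pts[chosen[-1]][None, :]).ravel()
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, cdist(pts, pts[nxt][None, :]).ravel())
    return pts[np.array(chosen)]
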