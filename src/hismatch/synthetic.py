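"""Synthetic electrophysiology cohort: a closed-form simulator stand-in.

The functions here replace the expensive finite-element reaction-eikonal
simulations with a deterministic, smooth, closed-form map from the
14-dimensional parameter space (9 anatomy mode weights + 5 EP parameters)
to four biomarkers, so the full history-matching pipeline is testable end
to end with known ground truth and zero external data.

The forms are structurally motivated rather than physiological fits:
activation time scales with heart size over conduction velocity, a thicker
or faster fast-endocardial-conduction (FEC) layer shortens endocardial
activation, and anatomy is dominated by the leading shape modes (mirroring
the variance ordering of a PCA-based shape model).  No attempt is made to
match finite-element outputs numerically.

Biomarkers (all positive; TAT_LV_endo < TAT by construction):

- ``TAT``          total biventricular activation time, ms
- ``TAT_LV_endo``  LV endocardial activation time, ms
- ``LV_mass``      left-ventricular mass, g
- ``LV_dim``       a synthetic LV dimension, mm
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .history_matching import TargetSpec, make_targets_from_values
from .parameter_space import DesignMatrix, ParameterSpace, UNIT

__all__ = [
    "BIOMARKER_NAMES",
    "SyntheticPatient",
    "simulate_biomarkers",
    "make_simulator",
    "make_patient",
    "make_cohort",
    "l1_farthest",
]

BIOMARKER_NAMES = ("TAT", "TAT_LV_endo", "LV_mass", "LV_dim")

#: size-factor weights for modes 1..9 (leading modes dominate)
_MODE_W = np.array([0.40, 0.23, 0.14, 0.09, 0.05, 0.04, 0.03, 0.02])


def _unit_points(space: ParameterSpace, X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        if X.frame != UNIT:
            X = space.to_unit(X)
        pts = X.points
    else:
        pts = np.atleast_2d(np.asarray(X, dtype=float))
    if pts.shape[1] != 14:
        raise ValueError(f"expected 14 input dimensions, got {pts.shape[1]}")
    if (pts < -1e-12).any() or (pts > 1 + 1e-12).any():
        raise ValueError("unit-frame design contains entries outside [0, 1]")
    return pts


def simulate_biomarkers(space: ParameterSpace, X) -> pd.DataFrame:
    """Deterministic biomarkers for each row of a unit-frame design.

    Columns ``u1..u9`` are the shape-mode weights; ``u10..u14`` map to
    fibre angle, FEC height, CV, k_xf and k_FEC in that order.
    """
    u = _unit_points(space, X)
    # heart-size factor driven by the shape modes (u6*u7 adds an interaction)
    s = 1.0 + 0.35 * (
        u[:, :5] @ _MODE_W[:5]
        + _MODE_W[5] * u[:, 5] * u[:, 6]
        + _MODE_W[6] * u[:, 7]
        + _MODE_W[7] * u[:, 8]
    )
    cv = 0.64 + 0.28 * u[:, 11]
    k_xf = 0.11 + 0.24 * u[:, 12]
    k_fec = 1.1 + 7.65 * u[:, 13]
    tat = (
        55.0 * s / cv
        * (1.0 + 0.08 * (1.0 - k_xf / 0.35))
        * (1.0 - 0.10 * (1.0 - 1.0 / k_fec))
    )
    endo_frac = 0.20 + 0.25 * (1.0 - u[:, 10]) * (1.0 - 0.5 * u[:, 13]) + 0.05 * (
        1.0 - u[:, 9]
    )
    return pd.DataFrame(
        {
            "TAT": tat,
            "TAT_LV_endo": tat * endo_frac,
            "LV_mass": 90.0 * s**1.7,
            "LV_dim": 42.0 + 18.0 * (0.6 * u[:, 0] + 0.4 * u[:, 2]),
        }
    )


def make_simulator(space: ParameterSpace):
    """A natural-frame simulator callback with a call counter.

    Returns a callable mapping an ``n x 14`` natural-frame matrix to the
    biomarker DataFrame; ``sim.n_calls`` counts invocations so workflows
    that promise zero simulations can be audited.
    """

    def sim(X_natural: np.ndarray) -> pd.DataFrame:
        sim.n_calls += 1
        sim.n_points += np.atleast_2d(X_natural).shape[0]
        return simulate_biomarkers(space, space.to_unit(np.atleast_2d(X_natural)))

    sim.n_calls = 0
    sim.n_points = 0
    return sim


@dataclass(frozen=True)
class SyntheticPatient:
    """Ground-truth parameters with exactly-consistent biomarkers and targets."""

    id: str
    u_star: np.ndarray
    biomarkers: pd.Series
    targets: TargetSpec
    c: float


def make_patient(
    space: ParameterSpace,
    seed: int = None,
    u_star: np.ndarray = None,
    c: float = 0.10,
    patient_id: str = "#01",
) -> SyntheticPatient:
    """A synthetic patient: draw (or accept) u*, simulate, derive targets.

    Drawn truths are uniform on ``[0.15, 0.85]^14`` to keep them away from
    the box boundary, where emulator extrapolation is least reliable;
    target SDs are ``c`` times each biomarker mean.
    """
    if u_star is None:
        if seed is None:
            raise ValueError("provide either seed or u_star")
        rng = np.random.default_rng(seed)
        u_star = 0.15 + 0.70 * rng.random(14)
    u_star = np.asarray(u_star, dtype=float).ravel()
    if u_star.size != 14 or (u_star < 0).any() or (u_star > 1).any():
        raise ValueError("u_star must be a 14-vector inside the unit cube")
    bio = simulate_biomarkers(space, u_star[None, :]).iloc[0]
    targets = make_targets_from_values(list(bio.index), bio.to_numpy(), c)
    return SyntheticPatient(id=patient_id, u_star=u_star, biomarkers=bio,
                            targets=targets, c=c)


def make_cohort(space: ParameterSpace, n: int, seed: int, c: float = 0.10):
    """``n`` seeded patients with zero-padded ids ``#01..#n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    width = max(2, len(str(n)))
    return [
        make_patient(space, seed=seed + i, c=c, patient_id=f"#{i + 1:0{width}d}")
        for i in range(n)
    ]


def l1_farthest(cohort, index: int, mode: str = "input") -> str:
    """Id of the cohort member with the largest l1 distance from ``cohort[index]``.

    ``mode="input"`` compares unit-frame ground-truth parameter vectors;
    ``mode="biomarker"`` compares biomarker vectors z-scored across the
    cohort so no single biomarker's units dominate.  Ties break to the
    smallest id.
    """
    if not 0 <= index < len(cohort):
        raise IndexError("index out of range")
    if len(cohort) < 2:
        raise ValueError("cohort must have at least 2 members")
    if mode == "input":
        vecs = np.array([p.u_star for p in cohort])
    elif mode == "biomarker":
        vecs = np.array([p.biomarkers.to_numpy() for p in cohort])
        sd = vecs.std(axis=0)
        sd[sd == 0] = 1.0
        vecs = (vecs - vecs.mean(axis=0)) / sd
    else:
        raise ValueError("mode must be 'input' or 'biomarker'")
    dist = np.abs(vecs - vecs[index]).sum(axis=1)
    dist[index] = -np.inf
    best = np.nonzero(dist == dist.max())[0]
    return min(cohort[i].id for i in best)
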