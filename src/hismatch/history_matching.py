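"""Bayesian history matching: implausibility, waves, NROY bookkeeping.

History matching calibrates a simulator to observed targets
``mu_i +/- sigma_i`` by iteratively ruling out parameter-space regions.
Each iteration ("wave") trains one Gaussian-process emulator per biomarker
on the accumulated simulations, scores candidate points by the
implausibility

    I(x) = max_i |E[f_i(x)] - mu_i| / sqrt(Var[f_i(x)] + sigma_i^2)

and keeps the not-ruled-out-yet (NROY) region ``{x : I(x) < T}`` under the
wave's threshold ``T``.  Membership is cumulative: a point must pass every
wave's cut, so the NROY region can only shrink.  Thresholds default to
3.2 for the first two waves and 3.0 (the 3-sigma rule) for the final one.

The module is organised statsmodels-style: :class:`HistoryMatching` is the
model (space + simulator + targets + configuration) and its :meth:`fit`
returns a :class:`HistoryMatchingResults` carrying the per-wave emulator
banks, diagnostics, NROY statistics and a :meth:`summary` table.  A trained
bank can be reused to calibrate a *new* subject's targets with zero extra
simulations via :func:`reuse_calibrate`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    EmptyNROYError,
    SamplerConfig,
    cloud_sample,
    latin_hypercube,
    select_batch,
    sobol_points,
)
from .gp import EmulatorBank, fit_bank
from .parameter_space import ParameterSpace

__all__ = [
    "TargetSpec",
    "WaveConfig",
    "WaveState",
    "HistoryMatching",
    "HistoryMatchingResults",
    "implausibility",
    "make_targets_from_values",
    "variance_quotient",
    "vq_stats",
    "nroy_agreement",
    "AgreementResult",
    "reuse_calibrate",
    "ReuseResult",
    "uncertainty_sensitivity",
    "frequency_map",
]


# ----------------------------------------------------------------------
# targets
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSpec:
    """Per-biomarker calibration targets ``mu_i +/- sigma_i`` (natural units)."""

    biomarker_names: tuple
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.biomarker_names)
        mu = np.asarray(self.mu, dtype=float).ravel()
        sigma = np.asarray(self.sigma, dtype=float).ravel()
        if len(set(names)) != len(names):
            raise ValueError("biomarker names must be unique")
        if not (len(names) == mu.size == sigma.size):
            raise ValueError("names, mu and sigma must have equal length")
        if (sigma <= 0).any():
            raise ValueError("every sigma_i must be strictly positive")
        object.__setattr__(self, "biomarker_names", names)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def m(self) -> int:
        return len(self.biomarker_names)

    def to_dict(self) -> dict:
        return {
            "biomarker_names": list(self.biomarker_names),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSpec":
        return cls(d["biomarker_names"], d["mu"], d["sigma"])


def make_targets_from_values(names, mu, c: float) -> TargetSpec:
    """Targets with SD a fixed fraction of the mean: ``sigma_i = c * |mu_i|``.

    Used when calibrating to deterministic simulation outputs, which carry
    no sampling variance of their own; ``c = 0.10`` is the default
    "high-uncertainty" setting and ``c = 0.05`` the "low-uncertainty" one.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    if c <= 0:
        raise ValueError("c must be positive")
    if (mu == 0).any():
        raise ValueError("zero-mean biomarker would give a degenerate sigma = 0")
    return TargetSpec(tuple(names), mu, c * np.abs(mu))


# ----------------------------------------------------------------------
# scores
# ----------------------------------------------------------------------


def implausibility(bank: EmulatorBank, targets: TargetSpec, X: np.ndarray) -> np.ndarray:
    """``I(x) = max_i |E[f_i] - mu_i| / sqrt(Var[f_i] + sigma_i^2)`` per row."""
    missing = set(targets.biomarker_names) - set(bank.biomarker_names)
    if missing:
        raise KeyError(f"bank has no emulator for biomarkers {sorted(missing)}")
    mean, var = bank.predict(X, names=targets.biomarker_names)
    z = np.abs(mean - targets.mu) / np.sqrt(var + targets.sigma**2)
    return z.max(axis=1)


def variance_quotient(bank: EmulatorBank, targets: TargetSpec, X: np.ndarray) -> np.ndarray:
    """``VQ(x) = max_i Var[f_i(x)] / sigma_i^2`` — emulator vs data variance."""
    missing = set(targets.biomarker_names) - set(bank.biomarker_names)
    if missing:
        raise KeyError(f"bank has no emulator for biomarkers {sorted(missing)}")
    _, var = bank.predict(X, names=targets.biomarker_names)
    return (var / targets.sigma**2).max(axis=1)


def vq_stats(bank: EmulatorBank, targets: TargetSpec, X_nroy: np.ndarray):
    """(max, median) of the variance quotient over the given NROY points."""
    X_nroy = np.atleast_2d(np.asarray(X_nroy, dtype=float))
    if X_nroy.shape[0] == 0:
        return (np.nan, np.nan)
    vq = variance_quotient(bank, targets, X_nroy)
    return (float(vq.max()), float(np.median(vq)))


@dataclass(frozen=True)
class AgreementResult:
    """Mask agreement; ``nroy_pct`` is None when A keeps no points."""

    whole_space_pct: float
    nroy_pct: float | None


def nroy_agreement(mask_a: np.ndarray, mask_b: np.ndarray) -> AgreementResult:
    """Agreement of two NROY masks over the same reference set.

    ``whole_space_pct``: % of reference points with equal status (both kept
    or both ruled out).  ``nroy_pct``: % of A's NROY points also kept by B;
    not applicable (None) when A keeps nothing.
    """
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.size != b.size:
        raise ValueError("masks must cover the same reference set")
    whole = 100.0 * float(np.count_nonzero(a == b)) / a.size
    if not a.any():
        return AgreementResult(whole, None)
    nroy = 100.0 * float(np.count_nonzero(a & b)) / float(np.count_nonzero(a))
    return AgreementResult(whole, nroy)


def frequency_map(nroy_points, space: ParameterSpace, n_bins: int = 20) -> pd.DataFrame:
    """Per-parameter NROY occupancy histogram over each full natural range.

    Returns a tidy DataFrame with columns ``parameter, bin_left, bin_right,
    proportion``; proportions sum to 1 within each parameter.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pts = np.atleast_2d(np.asarray(nroy_points, dtype=float))
    if pts.shape[0] == 0:
        warnings.warn("empty NROY region: frequency map is empty", RuntimeWarning,
                      stacklevel=2)
        return pd.DataFrame(columns=["parameter", "bin_left", "bin_right", "proportion"])
    rows = []
    for j, name in enumerate(space.names):
        edges_u = np.linspace(0.0, 1.0, n_bins + 1)
        counts, _ = np.histogram(pts[:, j], bins=edges_u)
        edges_nat = space.lower[j] + edges_u * space.span[j]
        prop = counts / counts.sum()
        for k in range(n_bins):
            rows.append((name, edges_nat[k], edges_nat[k + 1], prop[k]))
    return pd.DataFrame(rows, columns=["parameter", "bin_left", "bin_right", "proportion"])


# ----------------------------------------------------------------------
# configuration and per-wave state
# ----------------------------------------------------------------------


@dataclass
class WaveConfig:
    """Run sizes, thresholds and seeds for a history-matching run.

    Defaults reproduce the full-scale study conditions: a 438-point initial
    Latin hypercube design split 280/70/88 into train/validation/test, 140
    new simulations per wave, 10,000 emulated candidate points per wave and
    thresholds 3.2 / 3.2 / 3.0.
    """

    n_initial_train: int = 280
    n_initial_val: int = 70
    n_initial_test: int = 88
    n_per_wave: int = 140
    n_candidates: int = 10_000
    n_reference: int = 10_000
    thresholds: tuple = (3.2, 3.2, 3.0)
    seed: int = 0
    restarts: int = 10
    noise_free: bool = False
    cloud_scale: float = 0.05
    cloud_offspring: int = 5

    def __post_init__(self) -> None:
        counts = (self.n_initial_train, self.n_initial_val, self.n_initial_test,
                  self.n_per_wave, self.n_candidates, self.n_reference)
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        th = tuple(float(t) for t in self.thresholds)
        if len(th) == 0:
            raise ValueError("at least one threshold is required")
        if any(b > a + 1e-12 for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be non-increasing")
        self.thresholds = th

    @property
    def n_waves(self) -> int:
        return len(self.thresholds)

    def to_dict(self) -> dict:
        return {
            "n_initial_train": self.n_initial_train,
            "n_initial_val": self.n_initial_val,
            "n_initial_test": self.n_initial_test,
            "n_per_wave": self.n_per_wave,
            "n_candidates": self.n_candidates,
            "n_reference": self.n_reference,
            "thresholds": list(self.thresholds),
            "seed": self.seed,
            "restarts": self.restarts,
            "noise_free": self.noise_free,
            "cloud_scale": self.cloud_scale,
            "cloud_offspring": self.cloud_offspring,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WaveConfig":
        return cls(**{k: (tuple(v) if k == "thresholds" else v) for k, v in d.items()})


@dataclass
class WaveState:
    """State after one wave: the bank, its cut and the surviving candidates."""

    wave_index: int
    bank: EmulatorBank
    threshold: float
    candidates: np.ndarray | None
    implausibility: np.ndarray | None
    nroy_mask: np.ndarray | None
    scores: dict = field(default_factory=dict)
    n_new_simulations: int = 0
    candidates_capped: bool = False


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------


class HistoryMatching:
    """History-matching calibration model.

    Parameters
    ----------
    space : ParameterSpace
        The bounded input space; all sampling happens on its unit cube.
    simulator : callable
        Maps an ``n x d`` *natural-frame* parameter matrix to a DataFrame
        with one named column per biomarker.  Only called during
        :meth:`fit`; reuse workflows never touch it.
    targets : TargetSpec
        Calibration targets; biomarker names must be a subset of the
        simulator's output columns.
    config : WaveConfig
        Design sizes, thresholds and seeds.
    truth : array-like, optional
        A known ground-truth point (unit frame) whose implausibility is
        tracked per wave — available for synthetic-data validation.
    """

    def __init__(self, space: ParameterSpace, simulator, targets: TargetSpec,
                 config: WaveConfig = None, truth=None):
        self.space = space
        self.simulator = simulator
        self.targets = targets
        self.config = config if config is not None else WaveConfig()
        self.truth = None if truth is None else np.asarray(truth, dtype=float).ravel()

    # -- simulator plumbing -------------------------------------------------

    def _simulate(self, U: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
        """Run the simulator on unit-frame points; drop failing points."""
        X_nat = self.space.from_unit(U).points
        try:
            Y = self.simulator(X_nat)
            return U, Y.reset_index(drop=True)
        except Exception:
            ok_rows, ok_out = [], []
            for i in range(X_nat.shape[0]):
                try:
                    ok_out.append(self.simulator(X_nat[i:i + 1]).iloc[0])
                    ok_rows.append(i)
                except Exception as exc:
                    warnings.warn(
                        f"simulator failed at point {i}: {exc}; point dropped",
                        RuntimeWarning, stacklevel=2,
                    )
            if not ok_rows:
                raise RuntimeError("simulator failed on every point in the batch")
            return U[ok_rows], pd.DataFrame(ok_out).reset_index(drop=True)

    def _fit_bank(self, U, Y, wave, U_val, Y_val):
        cfg = self.config
        if U_val is None or U_val.shape[0] < 2:
            U_val = Y_val = None
        return fit_bank(
            U, Y[list(self.targets.biomarker_names)],
            noise_free=cfg.noise_free, restarts=cfg.restarts,
            seed=cfg.seed + 1000 * wave, provenance=f"wave{wave}",
            X_val=U_val, Y_val=Y_val,
        )

    # -- the full run -------------------------------------------------------

    def fit(self) -> "HistoryMatchingResults":
        """Run the initial design plus one wave per configured threshold.

        Wave 1 cuts a Sobol' candidate set with the initial-design bank and
        runs no extra simulations; each later wave simulates a maximin batch
        of ``n_per_wave`` NROY points, refits the bank on everything
        accumulated, repopulates the candidate set inside the current NROY
        region with the cloud technique and applies its threshold
        cumulatively.
        """
        space, cfg, targets = self.space, self.config, self.targets
        d = space.d

        n0 = cfg.n_initial_train + cfg.n_initial_val + cfg.n_initial_test
        U0 = latin_hypercube(d, n0, seed=cfg.seed)
        U0, Y0 = self._simulate(U0)
        n_tr = min(cfg.n_initial_train, U0.shape[0])
        n_val = min(cfg.n_initial_val, max(U0.shape[0] - n_tr, 0))
        U_tr, Y_tr = U0[:n_tr], Y0.iloc[:n_tr]
        U_val, Y_val = U0[n_tr:n_tr + n_val], Y0.iloc[n_tr:n_tr + n_val]
        U_te, Y_te = U0[n_tr + n_val:], Y0.iloc[n_tr + n_val:]

        ledger_U = [U0]
        ledger_Y = [Y0]
        acc_U, acc_Y = U_tr, Y_tr

        reference_set = sobol_points(d, cfg.n_reference, skip=0)

        waves: list[WaveState] = []
        for w, threshold in enumerate(cfg.thresholds, start=1):
            capped = False
            n_new = 0
            if w == 1:
                bank = self._fit_bank(acc_U, acc_Y, 0, U_val, Y_val)
                candidates = sobol_points(d, cfg.n_candidates, skip=cfg.n_reference)
                prev_keep = np.ones(candidates.shape[0], dtype=bool)
            else:
                prev = waves[-1]
                parents = prev.candidates[prev.nroy_mask]
                if parents.shape[0] == 0:
                    raise EmptyNROYError(
                        f"NROY region empty entering wave {w}; consider relaxing "
                        "the thresholds or enlarging the target uncertainties"
                    )
                batch = select_batch(parents, cfg.n_per_wave, seed=cfg.seed + 100 + w)
                Ub, Yb = self._simulate(batch)
                n_new = Ub.shape[0]
                ledger_U.append(Ub)
                ledger_Y.append(Yb)
                acc_U = np.vstack([acc_U, Ub])
                acc_Y = pd.concat([acc_Y, Yb], ignore_index=True)
                bank = self._fit_bank(acc_U, acc_Y, w, U_val, Y_val)

                prior_waves = waves

                def member(Xq, _pw=prior_waves):
                    keep = np.ones(Xq.shape[0], dtype=bool)
                    for ws in _pw:
                        keep[keep] &= (
                            implausibility(ws.bank, targets, Xq[keep]) < ws.threshold
                        )
                    return keep

                scfg = SamplerConfig(
                    seed=cfg.seed + 200 + w, cloud_scale=cfg.cloud_scale,
                    cloud_offspring=cfg.cloud_offspring,
                )
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", RuntimeWarning)
                    candidates = cloud_sample(parents, cfg.n_candidates, member, scfg)
                    capped = any("round cap" in str(c.message) for c in caught)
                prev_keep = np.ones(candidates.shape[0], dtype=bool)

            impl = implausibility(bank, targets, candidates)
            mask = prev_keep & (impl < threshold)
            scores = dict(bank.scores)
            if U_te.shape[0] >= 2:
                test_bank_scores = EmulatorBank(
                    bank.biomarker_names, bank.emulators, bank.provenance
                ).validate(U_te, Y_te[list(targets.biomarker_names)])
                bank.scores = scores  # keep validation scores on the bank
            else:
                test_bank_scores = {}
            waves.append(WaveState(
                wave_index=w, bank=bank, threshold=threshold,
                candidates=candidates, implausibility=impl, nroy_mask=mask,
                scores={"validation": scores, "test": test_bank_scores},
                n_new_simulations=n_new, candidates_capped=capped,
            ))

        ledger = self._make_ledger(np.vstack(ledger_U), pd.concat(ledger_Y, ignore_index=True))
        return HistoryMatchingResults(
            space=space, targets=targets, config=cfg, waves=waves,
            reference_set=reference_set, ledger=ledger, truth=self.truth,
        )

    def _make_ledger(self, U: np.ndarray, Y: pd.DataFrame) -> pd.DataFrame:
        X_nat = self.space.from_unit(U).points
        led = pd.DataFrame(X_nat, columns=list(self.space.names))
        return pd.concat([led, Y.reset_index(drop=True)], axis=1)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------


@dataclass
class HistoryMatchingResults:
    """Fitted history-matching run: banks, cuts, diagnostics, reports."""

    space: ParameterSpace
    targets: TargetSpec
    config: WaveConfig
    waves: list
    reference_set: np.ndarray
    ledger: pd.DataFrame
    truth: np.ndarray | None = None

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_simulations(self) -> int:
        return len(self.ledger)

    @property
    def final_bank(self) -> EmulatorBank:
        return self.waves[-1].bank

    # -- membership ---------------------------------------------------------

    def nroy_membership(self, X: np.ndarray, upto_wave: int = None) -> np.ndarray:
        """Cumulative membership: pass every wave's cut through ``upto_wave``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        upto = self.n_waves if upto_wave is None else upto_wave
        if upto > self.n_waves:
            raise ValueError(f"run has only {self.n_waves} waves")
        keep = np.ones(X.shape[0], dtype=bool)
        for ws in self.waves[:upto]:
            if not keep.any():
                break
            keep[keep] &= implausibility(ws.bank, self.targets, X[keep]) < ws.threshold
        return keep

    def reference_mask(self, upto_wave: int = None) -> np.ndarray:
        return self.nroy_membership(self.reference_set, upto_wave)

    def nroy_size(self, upto_wave: int = None) -> float:
        """NROY size as % of the original space (Monte-Carlo, fixed Sobol' set)."""
        mask = self.reference_mask(upto_wave)
        return 100.0 * float(np.count_nonzero(mask)) / mask.size

    def nroy_points(self, upto_wave: int = None) -> np.ndarray:
        return self.reference_set[self.reference_mask(upto_wave)]

    # -- diagnostics --------------------------------------------------------

    def implausibility_at(self, u, wave: int = None) -> float:
        """Implausibility of a unit-frame point under one wave's bank (default last)."""
        w = self.n_waves if wave is None else wave
        ws = self.waves[w - 1]
        return float(implausibility(ws.bank, self.targets,
                                    np.atleast_2d(np.asarray(u, dtype=float)))[0])

    def vq_stats(self, upto_wave: int = None) -> tuple[float, float]:
        """(max, median) variance quotient over the wave's NROY reference points."""
        w = self.n_waves if upto_wave is None else upto_wave
        return vq_stats(self.waves[w - 1].bank, self.targets, self.nroy_points(w))

    def frequency_map(self, n_bins: int = 20, upto_wave: int = None) -> pd.DataFrame:
        return frequency_map(self.nroy_points(upto_wave), self.space, n_bins)

    # -- reporting ----------------------------------------------------------

    def wave_report(self) -> pd.DataFrame:
        """One row per wave: NROY %, threshold, scores, VQ, I(truth)."""
        rows = []
        for ws in self.waves:
            w = ws.wave_index
            vmax, vmed = self.vq_stats(w)
            val = ws.scores.get("validation", {})
            row = {
                "wave": w,
                "threshold": ws.threshold,
                "n_new_simulations": ws.n_new_simulations,
                "nroy_pct": self.nroy_size(w),
                "vq_max": vmax,
                "vq_median": vmed,
                "r2_min": min((s["r2"] for s in val.values()), default=np.nan),
                "ise_min": min((s["ise"] for s in val.values()), default=np.nan),
            }
            if self.truth is not None:
                row["implausibility_truth"] = self.implausibility_at(self.truth, w)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """A plain-text run summary in the style of a model-results table."""
        rep = self.wave_report()
        lines = [
            "History Matching Results",
            "=" * 66,
            f"Parameter space: {self.space.d} dims; "
            f"biomarkers: {', '.join(self.targets.biomarker_names)}",
            f"Simulations used: {self.n_simulations}; "
            f"reference set: {self.reference_set.shape[0]} Sobol' points",
            "-" * 66,
        ]
        cols = [c for c in ("wave", "threshold", "n_new_simulations", "nroy_pct",
                            "vq_max", "vq_median", "r2_min", "ise_min",
                            "implausibility_truth") if c in rep.columns]
        lines.append(rep[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("=" * 66)
        per_bio = self.waves[-1].scores.get("validation", {})
        if per_bio:
            lines.append("Final-wave emulator validation (R^2 / ISE %):")
            for nm, s in per_bio.items():
                lines.append(f"  {nm:<14s} {s['r2']:.4f} / {s['ise']:.2f}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------

    def plot_frequency_maps(self, n_bins: int = 20, waves=None):
        """Bar-chart frequency maps per parameter, one panel per parameter."""
        import matplotlib.pyplot as plt

        waves = list(waves) if waves is not None else [self.n_waves]
        d = self.space.d
        ncols = min(5, d)
        nrows = -(-d // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                                 squeeze=False)
        for w in waves:
            fm = self.frequency_map(n_bins=n_bins, upto_wave=w)
            for j, name in enumerate(self.space.names):
                ax = axes[j // ncols][j % ncols]
                sub = fm[fm.parameter == name]
                centers = 0.5 * (sub.bin_left + sub.bin_right)
                width = (sub.bin_right - sub.bin_left).iloc[0]
                ax.bar(centers, sub.proportion, width=width, alpha=0.6,
                       label=f"wave {w}")
                ax.set_title(name, fontsize=9)
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        return fig

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        from . import runio

        runio.save_run(self, directory)

    # -- sensitivity helper -------------------------------------------------

    def rescored(self, targets: TargetSpec) -> "HistoryMatchingResults":
        """The same banks and cuts scored against different targets.

        No new simulations or fits: only the implausibility cuts change.
        Useful for scoring one trained run under shrunken uncertainties.
        """
        return replace(self, targets=targets)


def run_history_matching(space, simulator, targets, config=None,
                         truth=None) -> HistoryMatchingResults:
    """Functional alias: build a :class:`HistoryMatching` model and fit it."""
    return HistoryMatching(space, simulator, targets, config, truth=truth).fit()


# ----------------------------------------------------------------------
# reuse and sensitivity workflows
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ReuseResult:
    """Outcome of reusing a donor's emulators on a new subject's targets."""

    mask: np.ndarray
    nroy_pct: float
    implausibility_truth: float | None
    vq_max: float
    vq_median: float

    def to_dict(self) -> dict:
        return {
            "nroy_pct": self.nroy_pct,
            "implausibility_truth": self.implausibility_truth,
            "vq_max": self.vq_max,
            "vq_median": self.vq_median,
        }


def reuse_calibrate(
    donor_bank: EmulatorBank,
    recipient_targets: TargetSpec,
    reference_set: np.ndarray,
    threshold: float = 3.0,
    truth=None,
) -> ReuseResult:
    """Calibrate a new subject with a previously trained bank: zero simulations.

    A single implausibility pass of the reference set under the donor's
    emulators and the recipient's targets at the final threshold.  This is
    the bank-in-the-clinic scenario: a new patient is calibrated purely
    from existing simulation data.
    """
    impl = implausibility(donor_bank, recipient_targets, reference_set)
    mask = impl < threshold
    pct = 100.0 * float(np.count_nonzero(mask)) / mask.size
    vmax, vmed = vq_stats(donor_bank, recipient_targets, reference_set[mask])
    it = None
    if truth is not None:
        it = float(implausibility(donor_bank, recipient_targets,
                                  np.atleast_2d(np.asarray(truth, dtype=float)))[0])
    return ReuseResult(mask=mask, nroy_pct=pct, implausibility_truth=it,
                       vq_max=vmax, vq_median=vmed)


def uncertainty_sensitivity(run_factory, c_values=(0.10, 0.05)) -> pd.DataFrame:
    """Compare NROY regions across target-uncertainty settings.

    ``run_factory(c)`` must return a :class:`HistoryMatchingResults` for
    uncertainty fraction ``c`` under identical seeds, so the runs share the
    same reference set.  Reports, per pair (high c = H.U.C., low c =
    L.U.C.): whole-space overlap %, % of the low-uncertainty NROY inside
    the high-uncertainty NROY, and the converse, plus per-c NROY size and
    VQ stats.
    """
    cs = sorted(c_values, reverse=True)
    runs = {c: run_factory(c) for c in cs}
    ref = runs[cs[0]].reference_set
    for c in cs[1:]:
        if not np.array_equal(runs[c].reference_set, ref):
            raise ValueError("runs must share the same reference set (same seeds)")
    rows = []
    for hi, lo in zip(cs, cs[1:]):
        mh = runs[hi].reference_mask()
        ml = runs[lo].reference_mask()
        agree_hl = nroy_agreement(ml, mh)   # L.U.C. NROY inside H.U.C.
        agree_lh = nroy_agreement(mh, ml)   # H.U.C. NROY inside L.U.C.
        vh = runs[hi].vq_stats()
        vl = runs[lo].vq_stats()
        rows.append({
            "c_high": hi,
            "c_low": lo,
            "nroy_pct_huc": runs[hi].nroy_size(),
            "nroy_pct_luc": runs[lo].nroy_size(),
            "space_overlap_pct": agree_hl.whole_space_pct,
            "luc_in_huc_pct": agree_hl.nroy_pct,
            "huc_in_luc_pct": agree_lh.nroy_pct,
            "vq_max_huc": vh[0], "vq_median_huc": vh[1],
            "vq_max_luc": vl[0], "vq_median_luc": vl[1],
        })
    return pd.DataFrame(rows)
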