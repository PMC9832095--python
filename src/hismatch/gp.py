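"""Univariate Gaussian-process emulators with a fitted linear mean.

Each emulator is an exact GP surrogate for one scalar simulator output
(biomarker):

    f(x) = m(x) + g(x) + eps,        m(x) = beta0 + sum_i beta_i x_i,

where ``g`` is a zero-mean GP with the ARD squared-exponential (RBF)
kernel

    k(x, x') = sigma_f^2 * exp(-sum_i (x_i - x'_i)^2 / (2 delta_i^2))

and ``eps`` is iid Gaussian noise with variance ``sigma_n`` (zero in the
noise-free case, in which the emulator interpolates the training data with
zero predictive variance at the training points).

Kernel hyperparameters (delta, sigma_f, sigma_n) are fitted by multi-restart
L-BFGS maximization of the log-marginal likelihood in log-space with
analytic gradients; the mean coefficients (beta0, beta) are profiled out in
closed form at every step by generalized least squares, which is their exact
likelihood maximizer given the kernel.  Inputs are expected in the unit
hypercube; outputs are standardized internally for optimizer conditioning
and de-standardized on prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .design import latin_hypercube

__all__ = [
    "GPEmulator",
    "EmulatorBank",
    "fit_gpe",
    "fit_bank",
    "r2_score",
    "ise_score",
    "ConditioningError",
]

_JITTERS = (1e-10, 1e-8, 1e-6)


class ConditioningError(np.linalg.LinAlgError):
    """Training covariance not positive-definite after jitter escalation."""


def _sq_dists(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Per-dimension squared differences, shape (n1, n2, d)."""
    return (X1[:, None, :] - X2[None, :, :]) ** 2


def _kernel(sqd: np.ndarray, lengthscales: np.ndarray, outputscale: float) -> np.ndarray:
    return outputscale**2 * np.exp(-0.5 * (sqd / lengthscales**2).sum(axis=-1))


def _chol_with_jitter(K: np.ndarray, base: float):
    for jit in _JITTERS:
        jitter = max(jit, base)
        try:
            return cho_factor(K + jitter * np.eye(K.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            continue
    raise ConditioningError(
        "training covariance is not positive-definite even after jitter escalation"
    )


@dataclass
class GPEmulator:
    """A fitted exact-GP emulator for one biomarker.

    Hyperparameters are reported on the natural output scale:
    ``beta0`` + ``beta`` give the linear mean, ``lengthscales`` the ARD
    length-scales (unit-cube units), ``outputscale`` the kernel SD sigma_f
    and ``noise_var`` the noise variance sigma_n (0 for noise-free fits).
    """

    beta0: float
    beta: np.ndarray
    lengthscales: np.ndarray
    outputscale: float
    noise_var: float
    X_train: np.ndarray
    y_train: np.ndarray
    log_marginal_likelihood: float = np.nan
    name: str = ""
    # internal standardization and cached factorization
    _y_mean: float = 0.0
    _y_std: float = 1.0
    _jitter: float = field(default=1e-10, repr=False)
    _chol: object = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        noise_free: bool = False,
        restarts: int = 10,
        seed: int = 0,
        name: str = "",
    ) -> "GPEmulator":
        """Fit hyperparameters by maximizing the log-marginal likelihood.

        ``restarts`` independent L-BFGS runs are started from a default
        point plus LHS-drawn points in log-hyperparameter space; the run
        with the highest achieved likelihood wins.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if y.size != n:
            raise ValueError("X and y have inconsistent lengths")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("training data contain non-finite values")
        if n < d + 2:
            warnings.warn(
                f"only {n} training points for {d} dimensions; "
                "at least d + 2 are recommended",
                UserWarning,
                stacklevel=2,
            )
        if noise_free and len(np.unique(X.round(12), axis=0)) < n:
            warnings.warn(
                "duplicate training inputs with noise_free=True may make the "
                "covariance singular",
                UserWarning,
                stacklevel=2,
            )

        y_mean = float(y.mean())
        y_std = float(y.std())
        if y_std < 1e-12:
            y_std = 1.0
        ys = (y - y_mean) / y_std

        sqd = _sq_dists(X, X)
        H = np.column_stack([np.ones(n), X])

        # theta = [log delta (d), log sigma_f, (log sigma_n if noisy)]
        n_theta = d + 1 + (0 if noise_free else 1)
        bounds = [(np.log(1e-2), np.log(1e2))] * d + [(np.log(1e-3), np.log(1e3))]
        if not noise_free:
            bounds.append((np.log(1e-8), np.log(4.0)))

        def neg_logml(theta):
            val, grad = _logml_and_grad(theta, sqd, H, ys, noise_free)
            return -val, -grad

        starts = [np.concatenate([np.full(d, np.log(0.5)), [0.0]] + ([] if noise_free else [[np.log(1e-2)]]))]
        if restarts > 1:
            u = latin_hypercube(n_theta, restarts - 1, seed=seed)
            lo = np.array([np.log(0.1)] * d + [np.log(0.3)] + ([] if noise_free else [np.log(1e-6)]))
            hi = np.array([np.log(3.0)] * d + [np.log(3.0)] + ([] if noise_free else [np.log(0.1)]))
            starts += list(lo + u * (hi - lo))

        best_val, best_theta = -np.inf, starts[0]
        for s in starts:
            res = minimize(
                neg_logml, s, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 100},
            )
            if np.isfinite(res.fun) and -res.fun > best_val:
                best_val, best_theta = -res.fun, res.x

        delta = np.exp(best_theta[:d])
        sigma_f = float(np.exp(best_theta[d]))
        sigma_n = 0.0 if noise_free else float(np.exp(best_theta[d + 1]))

        gp = cls._build(
            X, ys, delta, sigma_f, sigma_n, sqd=sqd, H=H,
            y_mean=y_mean, y_std=y_std, name=name,
        )
        return gp

    @classmethod
    def from_hyperparameters(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        beta0: float,
        beta,
        lengthscales,
        outputscale: float,
        noise_var: float = 0.0,
        name: str = "",
    ) -> "GPEmulator":
        """Build an emulator with fixed hyperparameters (no optimization).

        Hyperparameters are interpreted on the natural output scale and no
        internal standardization is applied; the mean coefficients are taken
        as given rather than re-estimated.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        beta = np.asarray(beta, dtype=float).ravel()
        delta = np.broadcast_to(np.asarray(lengthscales, dtype=float).ravel(), (d,)).copy()
        sqd = _sq_dists(X, X)
        K = _kernel(sqd, delta, outputscale) + noise_var * np.eye(n)
        chol, jitter = _chol_with_jitter(K, 0.0)
        H = np.column_stack([np.ones(n), X])
        r = y - (beta0 + X @ beta)
        alpha = cho_solve(chol, r)
        logml = float(
            -0.5 * r @ alpha
            - np.log(np.diag(chol[0])).sum()
            - 0.5 * n * np.log(2 * np.pi)
        )
        return cls(
            beta0=float(beta0), beta=beta, lengthscales=delta,
            outputscale=float(outputscale), noise_var=float(noise_var),
            X_train=X, y_train=y, log_marginal_likelihood=logml, name=name,
            _y_mean=0.0, _y_std=1.0, _jitter=jitter, _chol=chol, _alpha=alpha,
        )

    @classmethod
    def _build(cls, X, ys, delta, sigma_f, sigma_n, sqd, H, y_mean, y_std, name):
        """Finalize a fit: profile beta by GLS and cache the factorization."""
        n = X.shape[0]
        K = _kernel(sqd, delta, sigma_f) + sigma_n * np.eye(n)
        chol, jitter = _chol_with_jitter(K, 0.0)
        Kinv_H = cho_solve(chol, H)
        Kinv_y = cho_solve(chol, ys)
        beta_full = np.linalg.solve(H.T @ Kinv_H, H.T @ Kinv_y)
        r = ys - H @ beta_full
        alpha = cho_solve(chol, r)
        logml = float(
            -0.5 * r @ alpha
            - np.log(np.diag(chol[0])).sum()
            - 0.5 * n * np.log(2 * np.pi)
        )
        return cls(
            beta0=y_mean + y_std * float(beta_full[0]),
            beta=y_std * beta_full[1:],
            lengthscales=np.asarray(delta, dtype=float),
            outputscale=y_std * sigma_f,
            noise_var=y_std**2 * sigma_n,
            X_train=X,
            y_train=y_mean + y_std * ys,
            log_marginal_likelihood=logml,
            name=name,
            _y_mean=y_mean, _y_std=y_std, _jitter=jitter,
            _chol=chol, _alpha=alpha,
        )

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and predictive variance (latent + noise) at ``X``.

        ``X`` is an ``n x d`` unit-frame matrix; returns two ``n``-vectors.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"expected {self.X_train.shape[1]} input dimensions, got {X.shape[1]}"
            )
        # internal (possibly standardized) scale
        sf_s = self.outputscale / self._y_std
        Ks = _kernel(_sq_dists(X, self.X_train), self.lengthscales, sf_s)
        mean_s = (
            (self.beta0 - self._y_mean) / self._y_std
            + X @ (self.beta / self._y_std)
            + Ks @ self._alpha
        )
        L = self._chol[0]
        v = solve_triangular(L, Ks.T, lower=True)
        var_s = sf_s**2 - (v**2).sum(axis=0) + self.noise_var / self._y_std**2
        var_s = np.maximum(var_s, 0.0)
        return self._y_mean + self._y_std * mean_s, self._y_std**2 * var_s

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "beta0": self.beta0,
            "beta": self.beta.tolist(),
            "lengthscales": self.lengthscales.tolist(),
            "outputscale": self.outputscale,
            "noise_var": self.noise_var,
            "y_mean": self._y_mean,
            "y_std": self._y_std,
            "log_marginal_likelihood": self.log_marginal_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict, X_train: np.ndarray, y_train: np.ndarray) -> "GPEmulator":
        X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
        y_train = np.asarray(y_train, dtype=float).ravel()
        y_std = d["y_std"]
        sf_s = d["outputscale"] / y_std
        delta = np.asarray(d["lengthscales"], dtype=float)
        n = X_train.shape[0]
        K = _kernel(_sq_dists(X_train, X_train), delta, sf_s) + (
            d["noise_var"] / y_std**2
        ) * np.eye(n)
        chol, jitter = _chol_with_jitter(K, 0.0)
        ys = (y_train - d["y_mean"]) / y_std
        beta = np.asarray(d["beta"], dtype=float)
        r = ys - ((d["beta0"] - d["y_mean"]) / y_std + X_train @ (beta / y_std))
        alpha = cho_solve(chol, r)
        return cls(
            beta0=d["beta0"], beta=beta, lengthscales=delta,
            outputscale=d["outputscale"], noise_var=d["noise_var"],
            X_train=X_train, y_train=y_train,
            log_marginal_likelihood=d.get("log_marginal_likelihood", np.nan),
            name=d.get("name", ""),
            _y_mean=d["y_mean"], _y_std=y_std, _jitter=jitter,
            _chol=chol, _alpha=alpha,
        )


def _logml_and_grad(theta, sqd, H, ys, noise_free):
    """Log-marginal likelihood (beta profiled out) and its theta-gradient."""
    n, d = H.shape[0], H.shape[1] - 1
    delta = np.exp(theta[:d])
    sigma_f = np.exp(theta[d])
    sigma_n = 0.0 if noise_free else np.exp(theta[d + 1])
    Kf = _kernel(sqd, delta, sigma_f)
    K = Kf + sigma_n * np.eye(n)
    try:
        chol, _ = _chol_with_jitter(K, 0.0)
    except ConditioningError:
        return -1e25, np.zeros_like(theta)
    Kinv_H = cho_solve(chol, H)
    Kinv_y = cho_solve(chol, ys)
    A = H.T @ Kinv_H
    try:
        beta = np.linalg.solve(A, H.T @ Kinv_y)
    except np.linalg.LinAlgError:
        return -1e25, np.zeros_like(theta)
    r = ys - H @ beta
    alpha = cho_solve(chol, r)
    logml = (
        -0.5 * r @ alpha - np.log(np.diag(chol[0])).sum() - 0.5 * n * np.log(2 * np.pi)
    )
    # gradient: 0.5 tr((alpha alpha^T - K^-1) dK); envelope theorem covers beta
    Kinv = cho_solve(chol, np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(theta)
    scaled = sqd / delta**2  # (n, n, d)
    WKf = W * Kf
    grad[:d] = 0.5 * np.einsum("ij,ijk->k", WKf, scaled)
    grad[d] = 0.5 * (WKf.sum()) * 2.0
    if not noise_free:
        grad[d + 1] = 0.5 * np.trace(W) * sigma_n
    return logml, grad


# ----------------------------------------------------------------------
# validation metrics
# ----------------------------------------------------------------------


def r2_score(y_pred_mean: np.ndarray, y_true: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_pred_mean = np.asarray(y_pred_mean, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_pred_mean.size != y_true.size or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 elements")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for constant y_true")
    ss_res = float(((y_true - y_pred_mean) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def ise_score(y_pred_mean, y_pred_sd, y_true) -> float:
    """Independent standard error: % of points with |mean - y| < 2 SD.

    The inequality is strict, so a degenerate SD of exactly zero counts as
    a failure even when the mean is exact.
    """
    m = np.asarray(y_pred_mean, dtype=float).ravel()
    s = np.asarray(y_pred_sd, dtype=float).ravel()
    y = np.asarray(y_true, dtype=float).ravel()
    if not (m.size == s.size == y.size):
        raise ValueError("inputs must have equal length")
    if (s < 0).any():
        raise ValueError("predictive SDs must be non-negative")
    return 100.0 * float(np.count_nonzero(np.abs(m - y) < 2.0 * s)) / m.size


# ----------------------------------------------------------------------
# banks
# ----------------------------------------------------------------------


@dataclass
class EmulatorBank:
    """One fitted :class:`GPEmulator` per biomarker, sharing the inputs."""

    biomarker_names: list
    emulators: list
    provenance: str = ""
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.biomarker_names) != len(self.emulators):
            raise ValueError("one emulator per biomarker name required")
        dims = {e.X_train.shape[1] for e in self.emulators}
        if len(dims) > 1:
            raise ValueError("all emulators in a bank must share the input dimension")

    def __getitem__(self, name: str) -> GPEmulator:
        return self.emulators[self.biomarker_names.index(name)]

    @property
    def d(self) -> int:
        return self.emulators[0].X_train.shape[1]

    def predict(self, X: np.ndarray, names=None) -> tuple[np.ndarray, np.ndarray]:
        """Stacked means and variances, shape (n, m), columns per biomarker."""
        names = list(names) if names is not None else self.biomarker_names
        means, variances = [], []
        for nm in names:
            mu, var = self[nm].predict(X)
            means.append(mu)
            variances.append(var)
        return np.column_stack(means), np.column_stack(variances)

    def validate(self, X_val: np.ndarray, Y_val: pd.DataFrame) -> dict:
        """Per-biomarker R^2 and ISE on a held-out design."""
        out = {}
        for nm in self.biomarker_names:
            mu, var = self[nm].predict(X_val)
            y = np.asarray(Y_val[nm], dtype=float)
            out[nm] = {
                "r2": r2_score(mu, y),
                "ise": ise_score(mu, np.sqrt(var), y),
            }
        self.scores = out
        return out

    # -- persistence: hyperparameters as JSON, training matrices as CSV ----

    def save(self, directory, name: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        X = self.emulators[0].X_train
        for e in self.emulators:
            if not np.array_equal(e.X_train, X):
                raise ValueError("bank save requires emulators sharing X_train")
        meta = {
            "provenance": self.provenance,
            "biomarker_names": list(self.biomarker_names),
            "emulators": [e.to_dict() for e in self.emulators],
            "scores": self.scores,
        }
        (directory / f"{name}.json").write_text(json.dumps(meta, indent=2))
        cols = {f"x{i}": X[:, i] for i in range(X.shape[1])}
        for nm, e in zip(self.biomarker_names, self.emulators):
            cols[f"y_{nm}"] = e.y_train
        pd.DataFrame(cols).to_csv(directory / f"{name}_train.csv", index=False)

    @classmethod
    def load(cls, directory, name: str) -> "EmulatorBank":
        directory = Path(directory)
        meta = json.loads((directory / f"{name}.json").read_text())
        train = pd.read_csv(directory / f"{name}_train.csv")
        xcols = [c for c in train.columns if c.startswith("x")]
        X = train[xcols].to_numpy(dtype=float)
        emulators = [
            GPEmulator.from_dict(ed, X, train[f"y_{nm}"].to_numpy(dtype=float))
            for nm, ed in zip(meta["biomarker_names"], meta["emulators"])
        ]
        return cls(
            biomarker_names=meta["biomarker_names"],
            emulators=emulators,
            provenance=meta.get("provenance", ""),
            scores=meta.get("scores", {}),
        )


def fit_gpe(X, y, noise_free: bool = False, restarts: int = 10, seed: int = 0,
            name: str = "") -> GPEmulator:
    """Functional alias for :meth:`GPEmulator.fit`."""
    return GPEmulator.fit(X, y, noise_free=noise_free, restarts=restarts,
                          seed=seed, name=name)


def fit_bank(
    X: np.ndarray,
    Y: pd.DataFrame,
    noise_free: bool = False,
    restarts: int = 10,
    seed: int = 0,
    provenance: str = "",
    X_val: np.ndarray = None,
    Y_val: pd.DataFrame = None,
) -> EmulatorBank:
    """Fit one independent emulator per named column of ``Y``.

    Per-biomarker fit errors are re-raised labeled with the biomarker name.
    When a validation design is supplied the bank records R^2 and ISE per
    biomarker in ``bank.scores``.
    """
    names = list(Y.columns)
    emulators = []
    for j, nm in enumerate(names):
        try:
            emulators.append(
                GPEmulator.fit(
                    X, np.asarray(Y[nm], dtype=float), noise_free=noise_free,
                    restarts=restarts, seed=seed + j, name=nm,
                )
            )
        except Exception as exc:
            raise type(exc)(f"fitting emulator for biomarker {nm!r}: {exc}") from exc
    bank = EmulatorBank(biomarker_names=names, emulators=emulators,
                        provenance=provenance)
    if X_val is not None and Y_val is not None:
        bank.validate(X_val, Y_val)
    return bank
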