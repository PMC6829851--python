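"""Logistic regression by iteratively reweighted least squares.

The comparator model for the genome scans: binary case/control status
regressed on allele count plus nuisance covariates (spline-encoded ages,
principal components).  Fitting is standard Fisher scoring / IRLS with
step-halving so the deviance never increases; perfect or quasi-perfect
separation is detected and flagged rather than silently producing huge
coefficients.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

from .exceptions import NonIdentifiableError

__all__ = ["Logistic", "LogisticResults", "fit_logistic"]

# fitted probabilities closer than this to 0/1 mark a saturated observation
_SATURATION_EPS = 1e-10


def _deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(mu) + (1 - y) * np.log1p(-mu)
    return -2.0 * float(np.sum(np.where(np.isfinite(ll), ll, 0.0)))


@dataclass
class LogisticResults:
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    deviance: float
    deviance_path: list
    llf: float
    n_iter: int
    converged: bool
    separated: bool
    nobs: int
    names: list = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "OR": self.odds_ratios,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.names or None,
        )

    def __repr__(self) -> str:
        head = (
            f"<LogisticResults n={self.nobs} deviance={self.deviance:.4f} "
            f"converged={self.converged} separated={self.separated}>"
        )
        return head + "\n" + self.summary().to_string()


class Logistic:
    """Binary-outcome logistic model ``logit P(y=1) = X beta``.

    ``X`` is the full design matrix; pass ``add_intercept=True`` (default)
    to prepend a constant column.
    """

    def __init__(self, y, X, add_intercept: bool = True, names=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(y):
            raise ValueError("design rows must match outcome length")
        if not np.all(np.isfinite(X)):
            raise ValueError("design must be finite")
        if not np.all(np.isin(y, [0.0, 1.0])):
            raise ValueError("outcome must be coded 0/1")
        if y.min() == y.max():
            raise ValueError("outcome contains a single class; cannot fit")
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        else:
            names = list(names)
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["const"] + names
        # at most one constant nonzero column is allowed (an intercept the
        # caller supplied); anything else is unidentifiable
        ptp = X.max(axis=0) - X.min(axis=0)
        const_cols = np.flatnonzero(ptp == 0)
        bad = [int(j) for j in const_cols if X[0, j] == 0.0]
        if len(const_cols) - len(bad) > 1:
            bad.extend(int(j) for j in const_cols[1:] if X[0, j] != 0.0)
        if bad:
            raise NonIdentifiableError(f"design column {bad[0]} is constant")
        self.y = y
        self.X = X
        self.names = names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariates,
                       add_intercept: bool = True) -> "Logistic":
        cols = [covariates] if isinstance(covariates, str) else list(covariates)
        return cls(df[outcome].to_numpy(), df[cols].to_numpy(float),
                   add_intercept=add_intercept, names=cols)

    def fit(self, tol: float = 1e-10, max_iter: int = 100,
            start_params=None) -> LogisticResults:
        X, y = self.X, self.y
        n, k = X.shape
        beta = (np.zeros(k) if start_params is None
                else np.asarray(start_params, dtype=float).copy())
        dev = _deviance(y, expit(X @ beta))
        path = [dev]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = X @ beta
            mu = expit(eta)
            w = mu * (1.0 - mu)
            w = np.clip(w, 1e-300, None)
            # Fisher scoring step via the weighted normal equations
            XtW = X.T * w
            H = XtW @ X
            g = X.T @ (y - mu)
            try:
                step = linalg.solve(H, g, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, g)[0]
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                dev_new = _deviance(y, expit(X @ cand))
                if np.isfinite(dev_new) and dev_new <= dev + 1e-12 * (1 + abs(dev)):
                    break
                factor *= 0.5
            beta = beta + factor * step
            path.append(dev_new)
            if abs(dev - dev_new) < tol * (1.0 + abs(dev)):
                dev = dev_new
                converged = True
                break
            dev = dev_new
        mu = expit(X @ beta)
        separated = bool(np.any(mu < _SATURATION_EPS) or np.any(mu > 1 - _SATURATION_EPS))
        w = np.clip(mu * (1.0 - mu), 1e-300, None)
        H = (X.T * w) @ X
        try:
            cov = linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            bse = np.full(k, np.nan)
        return LogisticResults(
            params=beta, bse=bse, cov_params=cov, deviance=dev,
            deviance_path=path, llf=-0.5 * dev, n_iter=n_iter,
            converged=converged and not separated, separated=separated,
            nobs=n, names=self.names,
        )


def fit_logistic(design, y, tol: float = 1e-10, max_iter: int = 100,
                 add_intercept: bool = False) -> LogisticResults:
    """Functional wrapper: IRLS fit of a fully specified design matrix.

    By convention the caller supplies the intercept column (matching the
    model-matrix contract); set ``add_intercept=True`` to prepend one.
    """
    return Logistic(y, design, add_intercept=add_intercept).fit(tol=tol, max_iter=max_iter)
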