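"""Restricted cubic spline design columns (Harrell truncated-power basis).

A restricted (natural) cubic spline with k knots is cubic between knots and
constrained to be *linear* beyond the boundary knots, which tames the wild
tail behaviour of unrestricted polynomials.  The basis has k-1 columns: the
identity plus k-2 nonlinear terms, each scaled by the squared knot span so
coefficients stay on a comparable scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "rcs_basis", "rcs_design"]

# Harrell's default knot placement quantiles by number of knots.
DEFAULT_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class SplineSpec:
    """Frozen description of a fitted spline basis (JSON-serializable)."""

    kind: str  # "restricted_cubic"
    knots: tuple

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def df(self) -> int:
        """Model degrees of freedom contributed (columns in the basis)."""
        return len(self.knots) - 1

    def to_dict(self) -> dict:
        return {"kind": self.kind, "knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(kind=d["kind"], knots=tuple(d["knots"]))


def _default_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    if n_knots not in DEFAULT_KNOT_QUANTILES:
        raise ValueError(f"no default knot quantiles for {n_knots} knots")
    q = DEFAULT_KNOT_QUANTILES[n_knots]
    return np.quantile(x, q)


def rcs_basis(x, n_knots: int = 5, knots=None):
    """Restricted cubic spline basis matrix for ``x``.

    Parameters
    ----------
    x : numeric vector
    n_knots : int
        Number of knots (>= 3); ignored when explicit ``knots`` are given.
    knots : sequence, optional
        Explicit strictly increasing knot locations in data units; the
        default places them at Harrell's quantiles of ``x``.

    Returns
    -------
    basis : (n, k-1) array
        Column 0 is ``x`` itself; columns 1..k-2 are the truncated-power
        nonlinear terms, linear beyond the boundary knots, normalized by
        the squared span of the knots.
    spec : SplineSpec
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if len(np.unique(x)) < n_knots:
            raise ValueError("not enough distinct values to place knots")
        t = _default_knots(x, n_knots)
    else:
        t = np.asarray(knots, dtype=float)
    if len(t) < 3:
        raise ValueError("a restricted cubic spline needs at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def plus3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + plus3(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        )
        cols.append(term / norm)
    return np.column_stack(cols), SplineSpec(kind="restricted_cubic", knots=tuple(t))


def rcs_design(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate an existing :class:`SplineSpec` basis at new data."""
    basis, _ = rcs_basis(x, knots=spec.knots)
    return basis
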