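"""Natural cubic regression-spline bases.

The basis follows the convention used throughout environmental time-series
epidemiology (R's ``splines::ns``): boundary knots at the minimum and maximum
of the covariate, ``df - 1`` interior knots at equally spaced quantiles, and a
natural constraint forcing the fitted curve to be linear beyond the boundary
knots.  A basis requested with ``df`` degrees of freedom has exactly ``df``
columns and, together with an intercept, contains every linear function of
the covariate.

The numerics are built on scipy's B-spline machinery; only the knot rule and
the natural (zero second derivative at the boundaries) constraint live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ConfigurationError, DegenerateDataError, RankDeficiencyError

__all__ = ["SplineSpec", "natural_spline_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of one natural cubic spline term.

    Parameters
    ----------
    df : int
        Degrees of freedom (number of basis columns).  Interior knots are
        placed at the ``df - 1`` equally spaced interior quantiles of the
        covariate; boundary knots at its min and max.
    """

    df: int
    knot_placement: str = "quantile"
    basis_kind: str = "natural-cubic"

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ConfigurationError(f"SplineSpec.df must be >= 1, got {self.df}")
        if self.knot_placement != "quantile":
            raise ConfigurationError(
                f"SplineSpec.knot_placement must be 'quantile', got {self.knot_placement!r}"
            )

    def knots(self, x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
        """Interior and boundary knots for covariate ``x`` under this spec."""
        lo, hi = float(np.min(x)), float(np.max(x))
        probs = np.linspace(0.0, 1.0, self.df + 1)[1:-1]
        interior = np.quantile(x, probs) if probs.size else np.empty(0)
        return np.asarray(interior, dtype=float), (lo, hi)


def _constrained_transform(aknots: np.ndarray, ncols: int) -> np.ndarray:
    """Null-space projector imposing zero second derivative at the boundaries.

    ``aknots`` is the full (replicated-boundary) knot vector; the returned
    matrix maps the raw cubic B-spline columns (first column dropped) onto the
    natural basis.
    """
    lo, hi = aknots[3], aknots[-4]
    const = np.empty((2, ncols))
    for j in range(ncols):
        coef = np.zeros(ncols + 1)
        coef[j + 1] = 1.0  # +1: the raw intercept column is dropped
        bj = BSpline(aknots, coef, 3, extrapolate=True)
        d2 = bj.derivative(2)
        const[0, j] = d2(lo)
        const[1, j] = d2(hi)
    # complete QR of the constraint rows; keep the orthogonal complement
    q, _ = np.linalg.qr(const.T, mode="complete")
    return q[:, 2:]


def natural_spline_basis(
    x: np.ndarray, spec: SplineSpec, anchor: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate the natural cubic spline basis of ``x`` under ``spec``.

    Returns an ``(n, spec.df)`` matrix.  Knots are placed from ``anchor``
    (default: ``x`` itself); pass the training covariate as ``anchor`` to
    evaluate the fitted basis at new points.  Values outside the boundary
    knots are extrapolated linearly (first-order Taylor expansion about the
    nearer boundary), which is what the natural constraint implies.

    Raises
    ------
    DegenerateDataError
        If the anchoring data are constant (no spline can be placed).
    RankDeficiencyError
        If ``df`` is too large for the number of anchoring observations.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("natural_spline_basis expects a 1-d covariate")
    anchor = x if anchor is None else np.asarray(anchor, dtype=float)
    if anchor.size < spec.df + 2:
        raise RankDeficiencyError(
            f"df={spec.df} requires at least {spec.df + 2} observations, got {anchor.size}"
        )
    if np.ptp(anchor) == 0:
        raise DegenerateDataError("covariate is constant; cannot place spline knots")

    interior, (lo, hi) = spec.knots(anchor)
    aknots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    ncols = interior.size + 3  # raw cubic columns after dropping the intercept column
    transform = _constrained_transform(aknots, ncols)

    inside = (x >= lo) & (x <= hi)
    out = np.empty((x.size, ncols))
    if inside.any():
        dm = BSpline.design_matrix(x[inside], aknots, 3, extrapolate=False).toarray()
        out[inside] = dm[:, 1:]
    if not inside.all():
        # linear extrapolation beyond the boundary knots
        for bound, mask in ((lo, x < lo), (hi, x > hi)):
            if not mask.any():
                continue
            v = np.zeros(ncols)
            d1 = np.zeros(ncols)
            for j in range(ncols):
                coef = np.zeros(ncols + 1)
                coef[j + 1] = 1.0
                bj = BSpline(aknots, coef, 3, extrapolate=True)
                v[j] = bj(bound)
                d1[j] = bj.derivative(1)(bound)
            out[mask] = v[None, :] + (x[mask] - bound)[:, None] * d1[None, :]
    basis = out @ transform
    assert basis.shape[1] == spec.df
    return basis
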