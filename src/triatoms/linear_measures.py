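"""Linear tripartite measures: partial correlation and variance partitioning.

Partial correlation PCorr(X, Z | Y) is the Pearson correlation between
the residuals of X and of Z after each has been regressed (least
squares, with intercept) on the confounder Y.

Variance partitioning (VP) decomposes the explained sum of squares of
the quadratic interacting regression

    Z ~ a*X + b*Y + c*X*Y     (all variables mean-centred)

into four nonnegative atoms via partial R^2: the unique atoms are the
explained variance lost when dropping the a*X or b*Y term, the
synergistic atom is the loss from dropping the interaction c*X*Y, and
the redundant atom is the classical commonality

    red * SST = SST - SSR_lin,x - SSR_lin,y + SSR_lin,{x,y}

computed from the three purely linear sub-models. All atoms are
normalised by the total sum of squares SST_Z, giving dimensionless
values; only relative comparisons of these values are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ATOM_NAMES",
    "DegenerateInputWarning",
    "VPAtoms",
    "partial_correlation",
    "pr_squared",
    "vp_atoms",
]

ATOM_NAMES = ("unq_x", "unq_y", "red", "syn")

_REL_TOL = 1e-12  # variance considered zero relative to total variance


class DegenerateInputWarning(UserWarning):
    """Raised when residual or total variance is numerically zero."""


@dataclass(frozen=True)
class VPAtoms:
    """Normalised variance-partitioning atoms plus fit diagnostics."""

    unq_x: float
    unq_y: float
    red: float
    syn: float
    sst: float
    a: float
    b: float
    c: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ATOM_NAMES}


def _residuals(target: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares residuals of target on design columns."""
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ coef


def partial_correlation(x, y, z) -> float:
    """Pearson correlation of X and Z after regressing out Y from both.

    Returns 0 (with a :class:`DegenerateInputWarning`) when either
    residual vector has near-zero variance, e.g. when X, Y, Z are
    perfectly redundant copies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValueError("x, y, z must have equal lengths")
    if n < 4:
        raise ValueError("need n >= 4 samples")

    design = np.column_stack([np.ones(n), y])
    rx = _residuals(x, design)
    rz = _residuals(z, design)
    tol = _REL_TOL * max(x.var(), z.var(), 1e-300)
    if rx.var() <= tol or rz.var() <= tol:
        warnings.warn(
            "residual variance is numerically zero; returning 0 by convention",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return 0.0
    r = float(np.corrcoef(rx, rz)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def pr_squared(ssr_reduced: float, ssr_full: float) -> float:
    """Partial R^2: residual sum of squares gained by the richer model.

    Nested least squares guarantees ssr_reduced >= ssr_full up to
    rounding, so tiny negative differences are clipped to 0.
    """
    if ssr_reduced < 0 or ssr_full < 0:
        raise ValueError("sums of squares must be nonnegative")
    return max(float(ssr_reduced) - float(ssr_full), 0.0)


def _ssr(target: np.ndarray, columns: list[np.ndarray]) -> float:
    if not columns:
        return float(target @ target)
    res = _residuals(target, np.column_stack(columns))
    return float(res @ res)


def vp_atoms(x, y, z) -> VPAtoms:
    """Variance-partitioning atoms of the quadratic interacting model.

    All variables (including the product predictor X*Y) are centred
    before fitting. Reduced models are re-fitted from scratch, and
    collinear designs are handled by minimum-norm least squares, so the
    atoms are well defined even for perfectly redundant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(z)
    if not (len(x) == len(y) == n):
        raise ValueError("x, y, z must have equal lengths")
    if n < 6:
        raise ValueError("need n >= 6 samples")

    xc = x - x.mean()
    yc = y - y.mean()
    zc = z - z.mean()
    xy = x * y
    xyc = xy - xy.mean()

    sst = float(zc @ zc)
    if sst <= _REL_TOL * n * max(z.var(), 1.0):
        warnings.warn(
            "total sum of squares is numerically zero; all atoms set to 0",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return VPAtoms(0.0, 0.0, 0.0, 0.0, sst, 0.0, 0.0, 0.0)

    full_design = np.column_stack([xc, yc, xyc])
    coef, *_ = np.linalg.lstsq(full_design, zc, rcond=None)
    res_full = zc - full_design @ coef
    ssr_full = float(res_full @ res_full)

    ssr_no_a = _ssr(zc, [yc, xyc])
    ssr_no_b = _ssr(zc, [xc, xyc])
    ssr_no_c = _ssr(zc, [xc, yc])
    ssr_lin_x = _ssr(zc, [xc])
    ssr_lin_y = _ssr(zc, [yc])
    ssr_lin_xy = ssr_no_c

    unq_x = pr_squared(ssr_no_a, ssr_full)
    unq_y = pr_squared(ssr_no_b, ssr_full)
    syn = pr_squared(ssr_no_c, ssr_full)
    # Commonality can come out negative in-sample (suppression); the atom
    # is defined as a nonnegative quantity, so negative values truncate to 0.
    red = max(sst - ssr_lin_x - ssr_lin_y + ssr_lin_xy, 0.0)

    unq_x, unq_y, red, syn = (v / sst for v in (unq_x, unq_y, red, syn))

    return VPAtoms(
        unq_x, unq_y, red, syn, sst, float(coef[0]), float(coef[1]), float(coef[2])
    )
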