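"""Sine leaf-shape model: fitting, goodness of fit, and area normalization.

The relative width of a grass leaf blade at relative distance ``l`` from the
tip is modelled as

    w(l) = sin(pi * l / (2 * a)) ** alpha

where ``a`` (the *ratio factor*, 0.5 < a <= 1) is the relative position of
maximum width measured from the tip, and ``alpha`` (the *shape factor*,
alpha > 0) controls how narrow the blade is: larger alpha gives a more
lanceolate outline, smaller alpha a more elliptical one.  The argument of the
sine is ``pi*l/(2a)`` so that the function attains its maximum value 1 exactly
at ``l = a``.

Integrating w over the blade gives the leaf-area coefficient ``c`` — the
fraction of the bounding rectangle (length x max width) occupied by the
blade, so that leaf area = c * length * width.  ``c`` is also used to rescale
leaf width so that leaves of different shape but equal length and
length-to-width ratio enclose identical area ("width adjustment").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "ShapeParams",
    "WidthProfile",
    "FitResult",
    "AreaCoefficient",
    "ParameterDomainError",
    "DegenerateLeafError",
    "FitError",
    "relative_width",
    "normalize_profile",
    "fit_shape",
    "goodness_of_fit",
    "area_coefficient",
    "adjusted_width",
    "leaf_area",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
]


class ParameterDomainError(ValueError):
    """Shape parameters outside the model's validity domain."""


class DegenerateLeafError(ValueError):
    """A width profile that cannot be normalized or fitted (e.g. all zero)."""


class FitError(RuntimeError):
    """Nonlinear least squares failed to produce any solution."""


# Fitter box: alpha in (0, 5], a in (0.5, 1].  The lower a-bound is open in
# the model; the solver uses a small offset.
_A_LO = 0.5 + 1e-9
DEFAULT_BOUNDS = ((1e-6, _A_LO), (5.0, 1.0))
DEFAULT_INIT = (0.85, 0.70)  # the fixed values commonly used for maize


@dataclass(frozen=True)
class ShapeParams:
    """Parameter pair of the sine leaf-shape function.

    alpha : shape factor, > 0 (narrowness exponent)
    a     : ratio factor, 0.5 < a <= 1 (relative tip distance of max width)
    """

    alpha: float
    a: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ParameterDomainError(f"alpha must be > 0, got {self.alpha}")
        if not (0.5 < self.a <= 1.0):
            raise ParameterDomainError(f"a must be in (0.5, 1], got {self.a}")


@dataclass
class WidthProfile:
    """Relative (length, width) samples along one blade, tip to base.

    ``rel_length`` is strictly increasing in [0, 1], measured from the leaf
    tip; ``rel_width`` is in [0, 1] with max 1 after normalization.
    """

    rel_length: np.ndarray
    rel_width: np.ndarray
    cultivar: str | None = None
    plant: str | None = None
    rank: int | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        self.rel_length = np.asarray(self.rel_length, dtype=float)
        self.rel_width = np.asarray(self.rel_width, dtype=float)
        if self.rel_length.size == 0 or self.rel_length.size != self.rel_width.size:
            raise ValueError("rel_length and rel_width must be equal-length, non-empty")
        if np.any(np.diff(self.rel_length) <= 0):
            raise ValueError("rel_length must be strictly increasing")

    def __len__(self) -> int:
        return int(self.rel_length.size)


@dataclass(frozen=True)
class FitResult:
    params: ShapeParams
    adj_r2: float
    rmse: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class AreaCoefficient:
    """Leaf-area coefficient c in (0, 1]: blade area / (length * max width)."""

    c: float
    steps: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.c <= 1):
            raise ParameterDomainError(f"c must be in (0, 1], got {self.c}")


def relative_width(l, p: ShapeParams):
    """Relative blade width at relative tip distance ``l`` in [0, 1].

    Vectorized over ``l``.  Returns values in [0, 1]; exactly 1 at ``l == a``.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0) or np.any(l > 1):
        raise ValueError("relative length must lie in [0, 1]")
    # a > 0.5 keeps the argument within [0, pi), so sin >= 0 on the domain
    w = np.sin(np.pi * l / (2.0 * p.a)) ** p.alpha
    return float(w) if w.ndim == 0 else w


def normalize_profile(
    lengths: Sequence[float],
    widths: Sequence[float],
    **ids,
) -> WidthProfile:
    """Normalize absolute (cm) samples by their maxima into a WidthProfile.

    Ties in the maximum are resolved by value only (division is by the max,
    so the first occurrence is as good as any); ordering is preserved.
    """
    lengths = np.asarray(lengths, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if lengths.size == 0 or lengths.size != widths.size:
        raise ValueError("lengths and widths must be equal-length, non-empty")
    lmax = lengths.max()
    wmax = widths.max()
    if lmax <= 0 or wmax <= 0:
        raise DegenerateLeafError("profile maxima must be positive")
    return WidthProfile(lengths / lmax, widths / wmax, **ids)


def goodness_of_fit(observed, estimated, n_params: int) -> tuple[float, float]:
    """Adjusted R-squared and RMSE of estimated vs observed values.

    R-squared is the coefficient of determination of the ordinary
    least-squares regression of observed on estimated values with intercept
    (equivalently, the squared Pearson correlation); a zero-variance estimate
    yields R-squared 0.  RMSE is the root mean squared direct residual
    observed - estimated.  adj R2 = 1 - (1 - R2)(n - 1)/(n - n_params - 1).
    """
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.size == 0 or obs.size != est.size:
        raise ValueError("observed and estimated must be equal-length, non-empty")
    n = obs.size
    if n <= n_params + 1:
        raise ValueError(f"need n > n_params + 1 points, got n={n}")
    rmse = float(np.sqrt(np.mean((obs - est) ** 2)))
    if np.var(est) == 0 or np.var(obs) == 0:
        r2 = 1.0 if rmse == 0 else 0.0
    else:
        r2 = float(np.corrcoef(obs, est)[0, 1] ** 2)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    return adj_r2, rmse


def _residuals(theta: np.ndarray, l: np.ndarray, w: np.ndarray) -> np.ndarray:
    alpha, a = theta
    return np.sin(np.pi * l / (2.0 * a)) ** alpha - w


def fit_shape(
    profile: WidthProfile,
    init: ShapeParams | tuple[float, float] | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
) -> FitResult:
    """Fit (alpha, a) to a width profile by bounded trust-region least squares.

    Starts from ``init`` (default (0.85, 0.70)); if the first start fails to
    converge, retries from the four corners of the parameter box and keeps
    the best local minimum.  The ``converged`` flag reports solver status
    honestly; non-convergence is flagged, never silent.
    """
    l = profile.rel_length
    w = profile.rel_width
    if len(profile) < 3:
        raise ValueError("need at least 3 points for a 2-parameter fit")
    if np.any(w < 0) or np.any(w > 1 + 1e-9):
        raise ValueError("relative widths must lie in [0, 1]")
    if np.all(w == 0):
        raise DegenerateLeafError("all-zero width profile cannot be fitted")

    if init is None:
        x0 = np.array(DEFAULT_INIT)
    elif isinstance(init, ShapeParams):
        x0 = np.array([init.alpha, init.a])
    else:
        x0 = np.asarray(init, dtype=float)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    def solve(x0):
        return optimize.least_squares(
            _residuals, np.clip(x0, lo, hi), bounds=(lo, hi), args=(l, w), method="trf"
        )

    best = solve(x0)
    if not best.success:
        eps = 1e-3
        corners = [
            (lo[0] + eps, lo[1] + eps),
            (lo[0] + eps, hi[1]),
            (hi[0], lo[1] + eps),
            (hi[0], hi[1]),
        ]
        for c in corners:
            res = solve(np.array(c))
            if res.success and (not best.success or res.cost < best.cost):
                best = res
    if best.x is None:  # pragma: no cover - scipy always returns x
        raise FitError("least squares produced no solution")

    alpha, a = best.x
    params = ShapeParams(float(alpha), float(min(a, 1.0)))
    est = relative_width(l, params)
    adj_r2, rmse = goodness_of_fit(w, est, n_params=2)
    return FitResult(params, adj_r2, rmse, len(profile), bool(best.success))


def area_coefficient(
    p: ShapeParams, steps: int = 100, rule: str = "riemann"
) -> AreaCoefficient:
    """Leaf-area coefficient: the shape function integrated over the blade.

    The default is a right-closed Riemann sum over ``steps`` equal steps,
    evaluating at l = 1/steps, 2/steps, ..., 1 (for steps=100: 0.01 ... 1.00)
    and averaging — the discretization conventionally used with this model.
    ``rule='trapezoid'`` integrates the same nodes (plus l=0) by the
    trapezoidal rule; ``rule='quad'`` uses adaptive quadrature.
    """
    if steps < 10:
        raise ValueError("steps must be >= 10")
    if rule == "quad":
        c, _ = integrate.quad(lambda x: relative_width(x, p), 0.0, 1.0)
        return AreaCoefficient(float(c), steps)
    nodes = np.arange(1, steps + 1) / steps
    w = relative_width(nodes, p)
    if rule == "riemann":
        c = float(np.mean(w))
    elif rule == "trapezoid":
        nodes = np.concatenate([[0.0], nodes])
        w = np.concatenate([[0.0], w])
        c = float(np.trapezoid(w, nodes))
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    return AreaCoefficient(c, steps)


def _coeff_value(c: AreaCoefficient | float) -> float:
    return c.c if isinstance(c, AreaCoefficient) else float(c)


def adjusted_width(leaf_length: float, lw_ratio: float, c: AreaCoefficient | float) -> float:
    """Shape-normalized maximum width: length * (1/LWRatio) * (0.75/c).

    Rescales width so that blades of any shape with the same length and
    length-to-width ratio enclose the same area as the reference shape with
    c = 0.75; width grows when c < 0.75 and shrinks when c > 0.75.
    """
    cval = _coeff_value(c)
    if leaf_length <= 0 or lw_ratio <= 0 or cval <= 0:
        raise ValueError("leaf_length, lw_ratio and c must be positive")
    return leaf_length * (1.0 / lw_ratio) * (0.75 / cval)


def leaf_area(length: float, width: float, c: AreaCoefficient | float) -> float:
    """Blade area = length * width * c."""
    cval = _coeff_value(c)
    if length <= 0 or width <= 0 or cval <= 0:
        raise ValueError("length, width and c must be positive")
    return length * width * cval
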