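"""Dose-response curve models and their closed-form log10-scale AUCs.

Two curve families are used throughout the package:

* :class:`CombinationCurve` — a four-parameter log-logistic
  ``y = y_min + (y_max - y_min) / (1 + 10**(lam * (m - x')))``
  fitted on log10 concentration ``x'``, used for the combination
  dose-response vectors of the cross design.
* :class:`MonotherapyCurve` — the three-parameter form with the bottom
  asymptote fixed at zero, ``y = a / (1 + 10**(b * (c - x')))``, used for
  single-drug responses.

Responses are handled internally as inhibition *fractions* in [0, 1];
the fitting entry points accept percent inhibition and rescale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from ._exceptions import FitError

LN10 = math.log(10.0)

#: below this absolute slope the curve is treated as flat (limit expressions)
FLAT_SLOPE = 1e-6

#: multi-start RSS below which further starts are skipped (noiseless data)
_EARLY_EXIT_RSS = 1e-14

_OPT_TOL = 1e-10  # ftol/xtol/gtol for the bounded least-squares solver


def _log1p10(t: np.ndarray | float) -> np.ndarray | float:
    """Overflow-safe ``log10(1 + 10**t)``."""
    return np.logaddexp(0.0, np.asarray(t, dtype=float) * LN10) / LN10


def four_pl(x: np.ndarray, y_lo: float, y_hi: float, m: float, lam: float) -> np.ndarray:
    """Four-parameter log-logistic on log10 concentration ``x``.

    ``y_lo`` is the left (low-concentration) asymptote and ``y_hi`` the right
    one; the curve is increasing when ``y_lo < y_hi`` for ``lam > 0``.
    """
    return y_lo + (y_hi - y_lo) * expit(lam * (np.asarray(x, float) - m) * LN10)


@dataclass(frozen=True)
class FitDiagnostics:
    rss: float = float("nan")
    converged: bool = False
    n_points: int = 0
    fallback: bool = False
    message: str = ""


def _default_diag() -> FitDiagnostics:
    return FitDiagnostics(rss=0.0, converged=True, n_points=0)


@dataclass(frozen=True)
class CombinationCurve:
    """Fitted four-parameter log-logistic combination dose-response curve.

    ``y_min``/``y_max`` are inhibition fractions with ``y_min <= y_max``;
    decreasing curves are encoded by a negative ``slope_lambda``.
    ``conc_range`` is the tested log10 concentration interval ``[c1, c2]``.
    """

    y_min: float
    y_max: float
    ic50: float
    slope_lambda: float
    conc_range: tuple[float, float]
    fit_diag: FitDiagnostics = field(default_factory=_default_diag)
    fallback_points: tuple[tuple[float, float], ...] | None = None

    @property
    def m(self) -> float:
        """log10(IC50), the curve midpoint on the log10 axis."""
        return math.log10(self.ic50)

    def predict(self, log10_conc):
        """Inhibition fraction at log10 concentration(s)."""
        return four_pl(log10_conc, self.y_min, self.y_max, self.m, self.slope_lambda)

    def predict_conc(self, conc):
        """Inhibition fraction at linear concentration(s) > 0."""
        return self.predict(np.log10(conc))

    def to_dict(self) -> dict:
        return {
            "y_min": self.y_min,
            "y_max": self.y_max,
            "ic50": self.ic50,
            "slope_lambda": self.slope_lambda,
            "conc_range": list(self.conc_range),
            "rss": self.fit_diag.rss,
            "converged": self.fit_diag.converged,
        }


@dataclass(frozen=True)
class MonotherapyCurve:
    """Fitted single-drug logistic with the bottom asymptote at zero.

    ``a`` is the top asymptote (fraction), ``b`` the slope and ``c`` the
    log10 midpoint concentration. ``b == 0`` is the flat limit where the
    curve is constant at ``a / 2``.
    """

    a: float
    b: float
    c: float
    conc_range: tuple[float, float]
    fit_diag: FitDiagnostics = field(default_factory=_default_diag)
    fallback_points: tuple[tuple[float, float], ...] | None = None

    @property
    def ic50(self) -> float:
        """Concentration at the half-maximal response, ``10**c``."""
        return 10.0 ** self.c

    def predict(self, log10_conc):
        return self.a * expit(self.b * (np.asarray(log10_conc, float) - self.c) * LN10)

    def predict_conc(self, conc):
        return self.predict(np.log10(conc))

    def as_combination_curve(self) -> CombinationCurve:
        """Equivalent four-parameter curve (y_min=0, y_max=a, lam=b, m=c)."""
        return CombinationCurve(
            y_min=0.0,
            y_max=self.a,
            ic50=10.0 ** self.c,
            slope_lambda=self.b,
            conc_range=self.conc_range,
            fit_diag=self.fit_diag,
            fallback_points=self.fallback_points,
        )

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "conc_range": list(self.conc_range),
            "rss": self.fit_diag.rss,
            "converged": self.fit_diag.converged,
        }


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def _logistic_auc(y_lo: float, y_hi: float, m: float, lam: float,
                  c1: float, c2: float) -> float:
    """Definite integral of the four-parameter log-logistic over [c1, c2]."""
    width = c2 - c1
    if y_lo == y_hi:
        return y_lo * width
    if abs(lam) < FLAT_SLOPE:
        # lam -> 0 limit: the curve is constant at the asymptote midpoint
        return y_lo * width + (y_hi - y_lo) * width / 2.0
    term = (_log1p10(lam * (c2 - m)) - _log1p10(lam * (c1 - m))) / lam
    return y_lo * width + (y_hi - y_lo) * float(term)


def _trapezoid_auc(points: tuple[tuple[float, float], ...]) -> float:
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    order = np.argsort(xs)
    return float(np.trapezoid(ys[order], xs[order]))


def combination_auc(curve: CombinationCurve) -> float:
    """Area under the curve over its log10 concentration range.

    Uses the closed form; falls back to the trapezoid on the observed points
    for curves flagged as unfittable.
    """
    if curve.fallback_points is not None:
        return _trapezoid_auc(curve.fallback_points)
    c1, c2 = curve.conc_range
    return _logistic_auc(curve.y_min, curve.y_max, curve.m, curve.slope_lambda, c1, c2)


def monotherapy_auc(curve: MonotherapyCurve) -> float:
    """Area under the monotherapy logistic over its log10 range."""
    if curve.fallback_points is not None:
        return _trapezoid_auc(curve.fallback_points)
    c1, c2 = curve.conc_range
    return _logistic_auc(0.0, curve.a, curve.c, curve.b, c1, c2)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _prepare_points(points) -> tuple[np.ndarray, np.ndarray]:
    """Validate (conc, %inhibition) pairs; return sorted (log10 conc, fraction)."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise FitError("need at least 2 (concentration, response) points")
    conc, resp = pts[:, 0], pts[:, 1]
    if not np.all(np.isfinite(pts)):
        raise FitError("non-finite concentration or response")
    if np.any(conc <= 0):
        raise FitError("all concentrations must be strictly positive")
    x = np.log10(conc)
    if np.unique(x).size < 2:
        raise FitError("need at least 2 distinct concentrations")
    y = np.clip(resp / 100.0, 0.0, 1.0)
    order = np.argsort(x)
    return x[order], y[order]


def _interp_midpoint(x: np.ndarray, y: np.ndarray) -> float:
    """Log10 concentration of the point closest to the half-response level."""
    level = (y.min() + y.max()) / 2.0
    return float(x[int(np.argmin(np.abs(y - level)))])


def _start_grid(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """Five (m, lam) multi-start pairs: quartile midpoints plus the
    response-interpolated midpoint, crossed with slopes {0.5, 1, 2}."""
    c1, c2 = float(x[0]), float(x[-1])
    width = c2 - c1
    m0 = _interp_midpoint(x, y)
    return [
        (m0, 1.0),
        (c1 + 0.25 * width, 0.5),
        (c1 + 0.50 * width, 1.0),
        (c1 + 0.75 * width, 2.0),
        (m0, 2.0),
    ]


def _is_increasing(x: np.ndarray, y: np.ndarray) -> bool:
    half = max(1, len(x) // 2)
    return float(np.mean(y[-half:])) >= float(np.mean(y[:half]))


def _multistart_lsq(residual, jac, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = least_squares(residual, x0, jac=jac, bounds=bounds,
                                ftol=_OPT_TOL, xtol=_OPT_TOL, gtol=_OPT_TOL,
                                max_nfev=200)
        except Exception:  # pragma: no cover - solver pathologies
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1]:
            best = (res, rss)
        if rss < _EARLY_EXIT_RSS:
            break
    return best


def fit_combination_curve(points) -> CombinationCurve:
    """Fit the four-parameter log-logistic to (conc, %inhibition) pairs.

    Responses are rescaled to fractions and clipped to [0, 1]. The
    parameter box is ``y_min, y_max in [0, 1]``, midpoint within
    ``[c1 - 2, c2 + 2]`` and ``|lambda| in [0.01, 20]``; decreasing data are
    fit with swapped asymptotes and reported with a negative slope. If the
    optimizer fails outright, a trapezoid-AUC fallback curve is returned
    with ``fit_diag.converged = False``.
    """
    x, y = _prepare_points(points)
    c1, c2 = float(x[0]), float(x[-1])
    conc_range = (c1, c2)
    n = len(x)

    if np.ptp(y) == 0.0:
        # degenerate: all responses identical -> flat curve at that value
        val = float(y[0])
        return CombinationCurve(
            y_min=val, y_max=val, ic50=10.0 ** ((c1 + c2) / 2.0),
            slope_lambda=0.0, conc_range=conc_range,
            fit_diag=FitDiagnostics(rss=0.0, converged=True, n_points=n,
                                    message="degenerate flat curve"),
        )

    increasing = _is_increasing(x, y)
    y_lo0 = float(y.min()) if increasing else float(y.max())
    y_hi0 = float(y.max()) if increasing else float(y.min())

    def residual(p):
        return four_pl(x, p[0], p[1], p[2], p[3]) - y

    def jacobian(p):
        y_lo, y_hi, m, lam = p
        s = expit(lam * (x - m) * LN10)
        ds = s * (1.0 - s) * LN10
        J = np.empty((n, 4))
        J[:, 0] = 1.0 - s
        J[:, 1] = s
        J[:, 2] = -(y_hi - y_lo) * lam * ds
        J[:, 3] = (y_hi - y_lo) * (x - m) * ds
        return J

    bounds = ([0.0, 0.0, c1 - 2.0, 0.01], [1.0, 1.0, c2 + 2.0, 20.0])
    starts = [np.array([y_lo0, y_hi0, m, lam]) for m, lam in _start_grid(x, y)]
    best = _multistart_lsq(residual, jacobian, starts, bounds)

    if best is None:  # pragma: no cover - least_squares essentially always returns
        warnings.warn("combination curve fit failed; using trapezoid fallback")
        return CombinationCurve(
            y_min=float(y.min()), y_max=float(y.max()),
            ic50=10.0 ** ((c1 + c2) / 2.0), slope_lambda=1.0,
            conc_range=conc_range,
            fit_diag=FitDiagnostics(rss=float("nan"), converged=False,
                                    n_points=n, fallback=True,
                                    message="optimizer failure"),
            fallback_points=tuple(zip(x.tolist(), y.tolist())),
        )

    res, rss = best
    y_lo, y_hi, m, lam = (float(v) for v in res.x)
    if y_lo <= y_hi:
        y_min, y_max, slope = y_lo, y_hi, lam
    else:
        # identical curve with swapped asymptotes and negated slope
        y_min, y_max, slope = y_hi, y_lo, -lam
        warnings.warn("fitted a decreasing combination dose-response curve")
    return CombinationCurve(
        y_min=y_min, y_max=y_max, ic50=10.0 ** m, slope_lambda=slope,
        conc_range=conc_range,
        fit_diag=FitDiagnostics(rss=rss, converged=bool(res.success), n_points=n),
    )


def fit_monotherapy_curve(points) -> MonotherapyCurve:
    """Fit the three-parameter logistic (bottom fixed at 0) to
    (conc, %inhibition) pairs; same conventions as
    :func:`fit_combination_curve`. The slope sign is unconstrained; a
    negative fitted slope (decreasing response) emits a warning.
    """
    x, y = _prepare_points(points)
    c1, c2 = float(x[0]), float(x[-1])
    conc_range = (c1, c2)
    mid = (c1 + c2) / 2.0
    n = len(x)

    if np.ptp(y) == 0.0:
        val = float(y[0])
        if val == 0.0:
            return MonotherapyCurve(
                a=0.0, b=0.0, c=mid, conc_range=conc_range,
                fit_diag=FitDiagnostics(rss=0.0, converged=True, n_points=n,
                                        message="degenerate zero curve"),
            )
        if val <= 0.5:
            # b -> 0 limit is constant at a/2, so a = 2 * value is exact
            return MonotherapyCurve(
                a=2.0 * val, b=0.0, c=mid, conc_range=conc_range,
                fit_diag=FitDiagnostics(rss=0.0, converged=True, n_points=n,
                                        message="degenerate flat curve"),
            )
        # constant above 0.5 cannot be represented exactly; fall through

    increasing = _is_increasing(x, y)
    sign = 1.0 if increasing else -1.0
    a0 = max(float(y.max()), 1e-3)

    def residual(p):
        return p[0] * expit(p[1] * (x - p[2]) * LN10) - y

    def jacobian(p):
        a, b, c = p
        s = expit(b * (x - c) * LN10)
        ds = s * (1.0 - s) * LN10
        J = np.empty((n, 3))
        J[:, 0] = s
        J[:, 1] = a * (x - c) * ds
        J[:, 2] = -a * b * ds
        return J

    bounds = ([0.0, -20.0, c1 - 2.0], [1.0, 20.0, c2 + 2.0])
    starts = [np.array([a0, sign * lam, m]) for m, lam in _start_grid(x, y)]
    best = _multistart_lsq(residual, jacobian, starts, bounds)

    if best is None:  # pragma: no cover
        warnings.warn("monotherapy curve fit failed; using trapezoid fallback")
        return MonotherapyCurve(
            a=float(y.max()), b=1.0, c=mid, conc_range=conc_range,
            fit_diag=FitDiagnostics(rss=float("nan"), converged=False,
                                    n_points=n, fallback=True,
                                    message="optimizer failure"),
            fallback_points=tuple(zip(x.tolist(), y.tolist())),
        )

    res, rss = best
    a, b, c = (float(v) for v in res.x)
    if b < 0:
        warnings.warn("fitted a decreasing monotherapy dose-response curve (b < 0)")
    return MonotherapyCurve(
        a=a, b=b, c=c, conc_range=conc_range,
        fit_diag=FitDiagnostics(rss=rss, converged=bool(res.success), n_points=n),
    )
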