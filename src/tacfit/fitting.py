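"""Nonlinear least-squares fitting of mono- and bi-exponential curves.

The fit pipeline mirrors standard practice in internal dosimetry: a
curve-stripping (exponential peeling) pass supplies starting values, and a
bounded trust-region least-squares refinement minimises the unweighted sum
of squared deviations.  Residuals are unweighted on purpose -- the
measurement uncertainties of the individual points are assumed unknown.

Bounds: amplitudes in [1e-6, 10]; rates in [lambda_phys(I-131), 10] 1/h.
The physical decay constant is a hard floor because a whole-body activity
fraction cannot decay slower than the radionuclide itself; without it a
fitted slow rate can collapse toward zero and send tau to absurd values.

The bi-exponential optimisation is started both from the stripping
estimate and from a perturbation of the mono-exponential optimum; the
better optimum is kept.  The second start makes the fitted models properly
nested (ss_BE <= ss_ME), which the model-selection statistics require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .models import (
    BEF,
    MEF,
    I131_PHYSICAL_LAMBDA,
    PARAM_INTERVALS,
    ExponentialParams,
    evaluate_fia,
)
from .simulate import TACPoints

__all__ = ["FitResult", "strip_estimates", "fit_model", "fit_both"]

AMP_BOUNDS = (1e-6, 10.0)
RATE_BOUNDS = (I131_PHYSICAL_LAMBDA, 10.0)

_COST_TOL = 1e-10
_MAX_ITER = 1000
_RESIDUAL_FLOOR = 1e-8  # clip for stripped residuals before taking logs


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit.

    ``ss`` is the sum of squared deviations at ``params``; ``df = n - k``
    the residual degrees of freedom; ``converged`` is False when the
    optimiser stopped on its iteration budget (the best point found is
    still returned, and model selection proceeds).
    """

    params: ExponentialParams
    ss: float
    df: int
    k: int
    converged: bool

    def __post_init__(self) -> None:
        if self.ss < 0:
            raise ValueError("ss must be >= 0")
        if self.df < 1:
            raise ValueError("need df = n - k >= 1")

    @property
    def n(self) -> int:
        return self.df + self.k


def _band_midpoint(kind: str) -> ExponentialParams:
    iv = PARAM_INTERVALS[kind]
    mids = {name: 0.5 * (lo + hi) for name, (lo, hi) in iv.items()}
    if kind == MEF:
        return ExponentialParams(MEF, (mids["A1"],), (mids["lambda1"],))
    return ExponentialParams(
        BEF, (mids["A1"], mids["A2"]), (mids["lambda1"], mids["lambda2"])
    )


def _loglinear(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Least-squares line through (t, ln y); returns (amplitude, rate)."""
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return float(np.exp(intercept)), float(-slope)


def strip_estimates(tac: TACPoints, kind: str) -> ExponentialParams:
    """Curve-stripping starting values for the least-squares fit.

    MEf: log-linear regression over all points.  BEf: the slow component is
    estimated from the last two points (the grid has a single late point,
    so the tail pair is what constrains it), its contribution is subtracted
    from the earlier points, and the clipped residuals give the fast
    component by another log-linear fit.

    Degenerate data (non-decaying, constant) fall back to the band
    midpoint rather than raising.
    """
    t, y = tac.times, tac.fia
    min_pts = 3 if kind == MEF else 5
    if tac.n < min_pts:
        raise ValueError(f"{kind} stripping needs >= {min_pts} points, got {tac.n}")
    try:
        if kind == MEF:
            a, lam = _loglinear(t, y)
            if lam <= 0 or not np.isfinite([a, lam]).all():
                return _band_midpoint(MEF)
            return ExponentialParams(MEF, (a,), (lam,))
        a2, lam2 = _loglinear(t[-2:], y[-2:])
        if lam2 <= 0 or not np.isfinite([a2, lam2]).all():
            return _band_midpoint(BEF)
        resid = y[:-2] - a2 * np.exp(-lam2 * t[:-2])
        resid = np.clip(resid, _RESIDUAL_FLOOR, None)
        a1, lam1 = _loglinear(t[:-2], resid)
        if lam1 <= 0 or not np.isfinite([a1, lam1]).all():
            return _band_midpoint(BEF)
        if lam1 <= lam2:  # peeling picked components in the wrong order
            a1, lam1, a2, lam2 = a2, lam2, a1, lam1
        if lam1 <= lam2:
            return _band_midpoint(BEF)
        return ExponentialParams(BEF, (a1, a2), (lam1, lam2))
    except (np.linalg.LinAlgError, ValueError):
        return _band_midpoint(kind)


def _clip_to_bounds(theta: np.ndarray) -> np.ndarray:
    out = theta.copy()
    out[0::2] = np.clip(out[0::2], AMP_BOUNDS[0] * 1.01, AMP_BOUNDS[1] * 0.99)
    out[1::2] = np.clip(out[1::2], RATE_BOUNDS[0] * 1.01, RATE_BOUNDS[1] * 0.99)
    return out


def _bounds(k: int) -> Tuple[np.ndarray, np.ndarray]:
    lo = np.array([AMP_BOUNDS[0], RATE_BOUNDS[0]] * (k // 2))
    hi = np.array([AMP_BOUNDS[1], RATE_BOUNDS[1]] * (k // 2))
    return lo, hi


def _model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    return (theta[0::2, None] * np.exp(-theta[1::2, None] * t[None, :])).sum(axis=0)


def _refine(t: np.ndarray, y: np.ndarray, theta0: np.ndarray):
    res = least_squares(
        lambda th: _model(th, t) - y,
        _clip_to_bounds(theta0),
        bounds=_bounds(theta0.size),
        method="trf",
        ftol=_COST_TOL,
        xtol=_COST_TOL,
        gtol=_COST_TOL,
        max_nfev=_MAX_ITER,
    )
    ss = float(2.0 * res.cost)
    return res.x, ss, bool(res.status > 0)


def fit_model(
    tac: TACPoints, kind: str, init: Optional[ExponentialParams] = None
) -> FitResult:
    """Bounded trust-region least-squares fit of one model family.

    ``init`` defaults to the stripping estimate.  Raises ``ValueError``
    when the curve has fewer than k + 1 points.
    """
    k = 2 if kind == MEF else 4
    if tac.n < k + 1:
        raise ValueError(f"{kind} fit needs at least {k + 1} points, got {tac.n}")
    if init is None:
        init = strip_estimates(tac, kind)
    theta, ss, ok = _refine(tac.times, tac.fia, init.as_array())
    return FitResult(
        params=ExponentialParams.from_array(kind, theta),
        ss=ss,
        df=tac.n - k,
        k=k,
        converged=ok,
    )


def _me_seeded_be_init(me_params: ExponentialParams) -> ExponentialParams:
    """BEf start derived from the MEf optimum: split the amplitude and
    spread the rate, so the BEf fit can only improve on the MEf optimum."""
    a, lam = me_params.amplitudes[0], me_params.rates[0]
    theta = np.array([0.6 * a, 1.5 * lam, 0.4 * a, lam / 1.5])
    theta = _clip_to_bounds(theta)
    if theta[1] <= theta[3]:
        theta[1] = theta[3] * 1.5
    return ExponentialParams.from_array(BEF, theta)


def fit_both(tac: TACPoints) -> Tuple[FitResult, FitResult]:
    """Fit MEf and BEf to the same curve, enforcing proper nesting.

    The BEf fit is started from both the stripping estimate and a
    perturbation of the MEf optimum; the lower-ss optimum is returned, so
    ``ss_be <= ss_me`` up to optimiser tolerance.
    """
    fit_me = fit_model(tac, MEF)
    fit_be = fit_model(tac, BEF)
    alt = fit_model(tac, BEF, init=_me_seeded_be_init(fit_me.params))
    if alt.ss < fit_be.ss:
        fit_be = alt
    if fit_be.ss > fit_me.ss:
        # rare: both starts found local optima above the MEf optimum; start
        # a BEf refinement at the MEf optimum itself (split infinitesimally)
        a, lam = fit_me.params.amplitudes[0], fit_me.params.rates[0]
        near = ExponentialParams.from_array(
            BEF, _clip_to_bounds(np.array([a * 0.999, lam * 1.001, a * 0.001, lam * 0.999]))
        )
        alt = fit_model(tac, BEF, init=near)
        if alt.ss < fit_be.ss:
            fit_be = alt
    return fit_me, fit_be
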