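"""Model selection between nested exponential fits.

Three classical routes for deciding between the mono-exponential (null)
and bi-exponential (alternative) description of a curve:

* corrected Akaike Information Criterion (AICc), valid from N >= 6 points
  for the 4-parameter model;
* Akaike weights derived from the AICc difference, usable either for a
  hard choice or for model-averaging tau;
* the extra-sum-of-squares F-test for nested least-squares models, valid
  from N >= 5 points.

All formulas operate on the unweighted sums of squared deviations of the
two fits.  K counts model parameters only (2 and 4), which is what sets
the applicability thresholds above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import f as f_distribution

from .fitting import FitResult
from .models import BEF, MEF

__all__ = [
    "NotApplicableError",
    "ModelSelection",
    "aicc_score",
    "akaike_weights",
    "aicc_select",
    "f_test_select",
    "tau_aicc_weighted",
    "min_points",
]


class NotApplicableError(ValueError):
    """A selection statistic is undefined for this number of points."""


#: Minimum number of curve points for each selection route.
_MIN_POINTS = {"FTest": 5, "AICc": 6, "AICcW": 6}


def min_points(method: str) -> int:
    """Smallest N at which a selection method is applicable."""
    return _MIN_POINTS[method]


@dataclass(frozen=True)
class ModelSelection:
    """A model choice together with the evidence that produced it."""

    chosen: str
    method: str
    aicc_me: Optional[float] = None
    aicc_be: Optional[float] = None
    w_me: Optional[float] = None
    w_be: Optional[float] = None
    f_stat: Optional[float] = None
    p_value: Optional[float] = None
    class_probs: Optional[Tuple[float, float]] = None  # (p_MEf, p_BEf)

    def __post_init__(self) -> None:
        if self.chosen not in (MEF, BEF):
            raise ValueError(f"unknown model kind {self.chosen!r}")
        if self.w_me is not None and abs(self.w_me + self.w_be - 1.0) > 1e-12:
            raise ValueError("Akaike weights must sum to 1")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def aicc_score(ss: float, n: int, k: int) -> float:
    """Corrected Akaike Information Criterion for a least-squares fit.

    AICc = N ln(SS/N) + 2K + 2K(K+1)/(N-K-1).  Undefined (raises
    :class:`NotApplicableError`) when N - K - 1 < 1.
    """
    if ss <= 0:
        raise ValueError("ss must be > 0")
    if n - k - 1 < 1:
        raise NotApplicableError(f"AICc undefined for N={n}, K={k} (N-K-1 < 1)")
    return n * float(np.log(ss / n)) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_me: float, aicc_be: float) -> Tuple[float, float]:
    """Akaike weights of the two candidate models.

    w_i = exp(-Delta_i/2) / (1 + exp(-Delta_i/2)) with Delta_i the signed
    AICc difference to the other model; the lower-AICc model receives the
    larger weight and the two weights sum to exactly 1.
    """
    if not (np.isfinite(aicc_me) and np.isfinite(aicc_be)):
        raise ValueError("AICc scores must be finite")
    delta = aicc_me - aicc_be
    # logistic(-delta/2), written to avoid overflow for large |delta|
    if delta >= 0:
        e = np.exp(-delta / 2.0)
        w_me = e / (1.0 + e)
    else:
        w_me = 1.0 / (1.0 + np.exp(delta / 2.0))
    return float(w_me), float(1.0 - w_me)


def aicc_select(fit_me: FitResult, fit_be: FitResult) -> ModelSelection:
    """Choose the model with the smaller AICc (ties go to the simpler MEf)."""
    n = fit_me.n
    a_me = aicc_score(fit_me.ss, n, fit_me.k)
    a_be = aicc_score(fit_be.ss, n, fit_be.k)
    w_me, w_be = akaike_weights(a_me, a_be)
    chosen = BEF if a_be < a_me else MEF
    return ModelSelection(
        chosen=chosen,
        method="AICc",
        aicc_me=a_me,
        aicc_be=a_be,
        w_me=w_me,
        w_be=w_be,
    )


def f_test_select(
    fit_me: FitResult, fit_be: FitResult, alpha: float = 0.05
) -> ModelSelection:
    """Extra-sum-of-squares F-test between the nested fits.

    F = ((SS_ME - SS_BE)/SS_BE) / ((DF_ME - DF_BE)/DF_BE), compared to the
    F(DF_ME - DF_BE, DF_BE) distribution.  The mono-exponential null is
    rejected (BEf chosen) iff p < alpha.  A negative numerator -- possible
    only through optimiser noise -- is clipped to zero.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df_me, df_be = fit_me.df, fit_be.df
    if df_be < 1:
        raise NotApplicableError(f"F-test undefined for N={fit_me.n} (DF_BE < 1)")
    d_df = df_me - df_be
    if fit_be.ss <= 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = max(fit_me.ss - fit_be.ss, 0.0) / fit_be.ss / (d_df / df_be)
        p = float(f_distribution.sf(f_stat, d_df, df_be))
    chosen = BEF if p < alpha else MEF
    return ModelSelection(chosen=chosen, method="FTest", f_stat=float(f_stat), p_value=p)


def tau_aicc_weighted(tau_me: float, tau_be: float, w_me: float, w_be: float) -> float:
    """Model-averaged tau: the Akaike-weight convex combination of the two
    per-model tau estimates (h)."""
    if abs(w_me + w_be - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(tau_me * w_me + tau_be * w_be)
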