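"""Exponential washout models for whole-body time-activity curves.

A whole-body time-activity curve (TAC) records the fraction of injected
activity (FIA) retained by the patient as a function of time after
administration.  For [131I]I-NaI therapy of metastatic differentiated
thyroid carcinoma the retention is well described by a sum of one or two
decaying exponentials,

    FIA(t) = sum_i A_i * exp(-lambda_i * t),

with dimensionless amplitudes ``A_i`` and washout rates ``lambda_i`` in
1/h.  The time-integrated activity coefficient is the area under the curve
from 0 to infinity,

    tau = sum_i A_i / lambda_i   [h],

which is proportional to the absorbed dose per unit administered activity.

This module holds the parameter container, the model evaluation, tau, and
the published parameter band for the two model families (mono-exponential,
``MEf``, and bi-exponential, ``BEf``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MEF",
    "BEF",
    "ExponentialParams",
    "evaluate_fia",
    "tau",
    "ME_LIMIT_LOWER",
    "ME_LIMIT_UPPER",
    "BE_LIMIT_LOWER",
    "BE_LIMIT_UPPER",
    "PARAM_INTERVALS",
    "I131_PHYSICAL_LAMBDA",
]

MEF = "MEf"
BEF = "BEf"

#: Physical decay constant of I-131 (half-life 8.02 d), 1/h.  Whole-body
#: FIA expressed in activity units cannot decay slower than physical decay,
#: so it is a hard lower bound for any fitted washout rate.
I131_PHYSICAL_LAMBDA = float(np.log(2.0) / (8.02 * 24.0))

# Limit curves of the published band of plausible whole-body curves.
# Each row is the full parameter vector (A_1, lambda_1[, A_2, lambda_2]) of
# one envelope curve; the "lower" curve decays fastest.  Note that for the
# bi-exponential family the slow amplitude of the lower curve (0.34) exceeds
# that of the upper curve (0.30): the rows are curves, not per-parameter
# minima/maxima.
ME_LIMIT_LOWER = (0.78, 0.0676)
ME_LIMIT_UPPER = (1.00, 0.0165)
BE_LIMIT_LOWER = (0.46, 0.1078, 0.34, 0.0476)
BE_LIMIT_UPPER = (0.70, 0.0225, 0.30, 0.0044)

#: Closed interval covered by each parameter between the two limit curves.
PARAM_INTERVALS = {
    MEF: {
        "A1": (0.78, 1.00),
        "lambda1": (0.0165, 0.0676),
    },
    BEF: {
        "A1": (0.46, 0.70),
        "lambda1": (0.0225, 0.1078),
        "A2": (0.30, 0.34),
        "lambda2": (0.0044, 0.0476),
    },
}


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of a mono- or bi-exponential FIA model.

    Parameters
    ----------
    kind : {"MEf", "BEf"}
        Model family.
    amplitudes : sequence of float
        Dimensionless amplitudes ``A_i``; length 1 (MEf) or 2 (BEf).
    rates : sequence of float
        Washout rates ``lambda_i`` in 1/h; same length as ``amplitudes``.
        For BEf the fast component comes first (``lambda1 > lambda2``).

    Notes
    -----
    Positivity and, for BEf, the fast-first rate ordering are enforced
    here.  Band membership is a property of the synthetic generator, not
    of the type: fitted parameters may legitimately leave the band.
    """

    kind: str
    amplitudes: tuple = field(default=())
    rates: tuple = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if self.kind not in (MEF, BEF):
            raise ValueError(f"unknown model kind {self.kind!r}")
        expected = 1 if self.kind == MEF else 2
        if len(self.amplitudes) != expected or len(self.rates) != expected:
            raise ValueError(
                f"{self.kind} requires {expected} amplitude/rate pair(s), got "
                f"{len(self.amplitudes)}/{len(self.rates)}"
            )
        if any(a <= 0 for a in self.amplitudes) or any(r <= 0 for r in self.rates):
            raise ValueError("amplitudes and rates must be strictly positive")
        if self.kind == BEF and not self.rates[0] > self.rates[1]:
            raise ValueError("BEf rates must be ordered fast-first (lambda1 > lambda2)")

    @property
    def k(self) -> int:
        """Number of fitted model parameters (2 for MEf, 4 for BEf)."""
        return 2 * len(self.amplitudes)

    def as_array(self) -> np.ndarray:
        """Interleaved (A_1, lambda_1[, A_2, lambda_2]) vector."""
        out = np.empty(self.k)
        out[0::2] = self.amplitudes
        out[1::2] = self.rates
        return out

    @classmethod
    def from_array(cls, kind: str, values: Sequence[float]) -> "ExponentialParams":
        """Build from an interleaved (A, lambda, ...) vector, ordering BEf
        components fast-first if needed."""
        v = np.asarray(values, dtype=float)
        amps, rates = v[0::2], v[1::2]
        if kind == BEF and rates[0] < rates[1]:
            amps, rates = amps[::-1], rates[::-1]
        return cls(kind, tuple(amps), tuple(rates))


def evaluate_fia(params: ExponentialParams, times) -> np.ndarray:
    """Evaluate FIA(t) = sum_i A_i exp(-lambda_i t) at the given times (h)."""
    t = np.asarray(times, dtype=float)
    amps = np.asarray(params.amplitudes)
    rates = np.asarray(params.rates)
    return (amps[:, None] * np.exp(-rates[:, None] * t[None, :])).sum(axis=0).reshape(t.shape)


def tau(params: ExponentialParams) -> float:
    """Time-integrated activity coefficient tau = sum_i A_i / lambda_i, in h."""
    return float(sum(a / r for a, r in zip(params.amplitudes, params.rates)))
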