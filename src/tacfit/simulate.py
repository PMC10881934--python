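"""Synthetic whole-body FIA curve generator.

Emulates the measurement protocol of an [131I]I-NaI therapy ward: the
patient is measured repeatedly during hospitalisation (first N-1 points
equally spaced over [0, 54] h) and once more at a late follow-up (160 h).
Curves are drawn from a band of plausible mono- and bi-exponential
retention curves bounded by two published limit curves per family; test
curves receive 5 % relative Gaussian noise emulating the repeatability of
dose-rate-derived FIA values.

Sampling law
------------
Each exponential component is interpolated uniformly between its value on
the lower-limit curve and its value on the upper-limit curve (one
independent interpolant per component).  This treats the published
parameter rows as what they are -- envelope curves -- and keeps every
noise-free curve inside the band.  Independent uniform per-parameter
sampling is available via ``coupling="independent"`` for sensitivity
studies; it produces a broader family that can leave the band envelope
and makes the two classes overlap in curve space.

Bi-exponential draws violating the fast-first rate ordering
(lambda1 > lambda2) or the FIA(0) <= 1 constraint (A1 + A2 <= 1) are
rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .models import (
    BE_LIMIT_LOWER,
    BE_LIMIT_UPPER,
    BEF,
    ME_LIMIT_LOWER,
    ME_LIMIT_UPPER,
    MEF,
    ExponentialParams,
    evaluate_fia,
    tau,
)

__all__ = [
    "TACPoints",
    "DatasetSpec",
    "TACDataset",
    "make_time_grid",
    "sample_parameters",
    "add_measurement_noise",
    "generate_dataset",
    "band_envelope",
]

LATE_TIME_H = 160.0
HOSPITAL_WINDOW_H = 54.0
MIN_POINTS = 4

_MAX_REJECTION_TRIES = 100_000


@dataclass(frozen=True)
class TACPoints:
    """One measured or simulated time-activity curve.

    ``times`` (h) strictly increasing, ``fia`` dimensionless and positive,
    ``truth`` carries the generating parameters when known.
    """

    times: np.ndarray
    fia: np.ndarray
    truth: Optional[ExponentialParams] = None
    noisy: bool = False
    curve_id: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fia, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fia", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and fia must be 1-D vectors of equal length")
        if t.size < MIN_POINTS:
            raise ValueError(f"a curve needs at least {MIN_POINTS} points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(y > 0):
            raise ValueError("all FIA values must be positive")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class DatasetSpec:
    """Configuration of one synthetic dataset.

    ``noise_sigma_rel`` is the relative standard deviation of the Gaussian
    measurement noise (0 for training sets, 0.05 for test sets).
    """

    n_points: int
    n_me: int
    n_be: int
    noise_sigma_rel: float = 0.0
    seed: int = 0
    coupling: str = "component"

    def __post_init__(self) -> None:
        if self.n_points < MIN_POINTS:
            raise ValueError(f"n_points must be >= {MIN_POINTS}")
        if self.n_me < 0 or self.n_be < 0 or self.n_me + self.n_be == 0:
            raise ValueError("need a positive number of curves")
        if self.noise_sigma_rel < 0:
            raise ValueError("noise_sigma_rel must be >= 0")
        if self.coupling not in ("component", "independent"):
            raise ValueError("coupling must be 'component' or 'independent'")


def make_time_grid(n_points: int) -> np.ndarray:
    """Measurement time grid: N-1 points equally spaced on [0, 54] h plus
    one late point at 160 h.

    >>> make_time_grid(4)
    array([  0.,  27.,  54., 160.])
    """
    if n_points < MIN_POINTS:
        raise ValueError(f"n_points must be >= {MIN_POINTS}, got {n_points}")
    return np.concatenate(
        [np.linspace(0.0, HOSPITAL_WINDOW_H, n_points - 1), [LATE_TIME_H]]
    )


def _interp_params(kind: str, u: np.ndarray) -> np.ndarray:
    """Parameter vector(s) at interpolants ``u`` (per-component columns)."""
    if kind == MEF:
        lo = np.asarray(ME_LIMIT_LOWER)
        hi = np.asarray(ME_LIMIT_UPPER)
        return lo + u[:, [0, 0]] * (hi - lo)
    lo = np.asarray(BE_LIMIT_LOWER)
    hi = np.asarray(BE_LIMIT_UPPER)
    return lo + u[:, [0, 0, 1, 1]] * (hi - lo)


def _uniform_params(kind: str, rng: np.random.Generator, size: int) -> np.ndarray:
    a, b = (
        (ME_LIMIT_LOWER, ME_LIMIT_UPPER) if kind == MEF else (BE_LIMIT_LOWER, BE_LIMIT_UPPER)
    )
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return rng.uniform(lo, hi, size=(size, len(lo)))


#: coarse grid used for the band-containment rejection of BEf draws
_CONTAINMENT_GRID = np.concatenate([np.linspace(0.0, 10.0, 41), np.linspace(10.5, 160.0, 60)])


def _inside_band(kind: str, cand: np.ndarray) -> np.ndarray:
    lo, hi = band_envelope(kind, _CONTAINMENT_GRID)
    amps, rates = cand[:, 0::2], cand[:, 1::2]
    y = np.einsum(
        "ck,ckt->ct",
        amps,
        np.exp(-rates[:, :, None] * _CONTAINMENT_GRID[None, None, :]),
    )
    return np.all(y >= lo - 1e-9, axis=1) & np.all(y <= hi + 1e-9, axis=1)


def _sample_matrix(
    kind: str, rng: np.random.Generator, size: int, coupling: str
) -> np.ndarray:
    """Draw ``size`` valid parameter vectors, rejecting invalid BEf draws.

    BEf rejection rules: fast-first rate ordering, FIA(0) <= 1, and (for
    the component-interpolating sampler, whose two interpolants are
    otherwise free to combine a weak fast component with a very slow
    tail) containment of the noise-free curve between the two limit
    curves of the band.
    """
    out = np.empty((0, 2 if kind == MEF else 4))
    tries = 0
    while out.shape[0] < size:
        tries += 1
        if tries > _MAX_REJECTION_TRIES:
            raise RuntimeError("parameter rejection sampling did not terminate")
        need = size - out.shape[0]
        if coupling == "component":
            u = rng.uniform(size=(need, 1 if kind == MEF else 2))
            cand = _interp_params(kind, u)
        else:
            cand = _uniform_params(kind, rng, need)
        if kind == BEF:
            ok = (cand[:, 1] > cand[:, 3]) & (cand[:, 0] + cand[:, 2] <= 1.0)
            if coupling == "component":
                ok &= _inside_band(BEF, cand)
            cand = cand[ok]
        out = np.vstack([out, cand])
    return out[:size]


def sample_parameters(
    kind: str,
    rng: np.random.Generator,
    coupling: str = "component",
) -> ExponentialParams:
    """Draw one in-band parameter set for the given model family."""
    row = _sample_matrix(kind, rng, 1, coupling)[0]
    return ExponentialParams.from_array(kind, row)


def add_measurement_noise(
    fia, sigma_rel: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian relative noise: each value y is replaced by N(y, sigma_rel*y).

    Non-positive draws are redrawn so the output stays physical (an FIA
    measurement is a positive count-derived quantity).
    """
    y = np.asarray(fia, dtype=float)
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be >= 0")
    if sigma_rel == 0:
        return y.copy()
    out = rng.normal(y, sigma_rel * y)
    for _ in range(_MAX_REJECTION_TRIES):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(y[bad], sigma_rel * y[bad])
    raise RuntimeError("noise positivity redraw did not terminate")


@dataclass
class TACDataset(Sequence):
    """A generated dataset: shared time grid plus one FIA row per curve.

    Behaves as a sequence of :class:`TACPoints`; the array attributes give
    the fast path used by the ML feature builders.
    """

    times: np.ndarray
    fia: np.ndarray
    kinds: np.ndarray
    truth_matrix: np.ndarray  # (n_curves, 4); MEf rows padded with NaN
    noisy: bool
    spec: DatasetSpec = None

    def __len__(self) -> int:
        return self.fia.shape[0]

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return TACPoints(
            times=self.times,
            fia=self.fia[i],
            truth=self.truth_params(i),
            noisy=self.noisy,
            curve_id=int(i),
        )

    def __iter__(self) -> Iterator[TACPoints]:
        return (self[i] for i in range(len(self)))

    def truth_params(self, i: int) -> ExponentialParams:
        row = self.truth_matrix[i]
        kind = str(self.kinds[i])
        return ExponentialParams.from_array(kind, row[: 2 if kind == MEF else 4])

    def true_tau(self) -> np.ndarray:
        """tau of the generating parameters, one value per curve (h)."""
        m = self.truth_matrix
        with np.errstate(invalid="ignore"):
            t = np.nansum(m[:, 0::2] / m[:, 1::2], axis=1)
        return t

    @property
    def n_points(self) -> int:
        return int(self.times.size)


def generate_dataset(spec: DatasetSpec, rng: Optional[np.random.Generator] = None) -> TACDataset:
    """Generate a full training or test dataset from its specification.

    MEf curves come first, then BEf curves.  Noise is applied iff
    ``spec.noise_sigma_rel > 0``.  Bit-reproducible from ``spec.seed`` when
    no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = make_time_grid(spec.n_points)
    pm = _sample_matrix(MEF, rng, spec.n_me, spec.coupling)
    pb = _sample_matrix(BEF, rng, spec.n_be, spec.coupling)

    truth = np.full((spec.n_me + spec.n_be, 4), np.nan)
    truth[: spec.n_me, :2] = pm
    truth[spec.n_me :, :4] = pb

    fia_me = pm[:, 0:1] * np.exp(-pm[:, 1:2] * t) if spec.n_me else np.empty((0, t.size))
    fia_be = (
        pb[:, 0:1] * np.exp(-pb[:, 1:2] * t) + pb[:, 2:3] * np.exp(-pb[:, 3:4] * t)
        if spec.n_be
        else np.empty((0, t.size))
    )
    fia = np.vstack([fia_me, fia_be])
    if spec.noise_sigma_rel > 0:
        fia = add_measurement_noise(fia, spec.noise_sigma_rel, rng)

    kinds = np.array([MEF] * spec.n_me + [BEF] * spec.n_be, dtype=object)
    return TACDataset(
        times=t,
        fia=fia,
        kinds=kinds,
        truth_matrix=truth,
        noisy=spec.noise_sigma_rel > 0,
        spec=spec,
    )


def band_envelope(kind: str, times) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper envelope curves of the band for one family."""
    lo_p, hi_p = (
        (ME_LIMIT_LOWER, ME_LIMIT_UPPER) if kind == MEF else (BE_LIMIT_LOWER, BE_LIMIT_UPPER)
    )
    lo = evaluate_fia(ExponentialParams.from_array(kind, lo_p), times)
    hi = evaluate_fia(ExponentialParams.from_array(kind, hi_p), times)
    return np.minimum(lo, hi), np.maximum(lo, hi)
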