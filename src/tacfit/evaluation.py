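"""Benchmarking of the model-selection and tau-estimation chains.

Two simulation tests, run for every configured number of curve points N:

* **Test 1 (error-free classification)** isolates estimation quality: each
  noisy test curve is processed with its *true* model class, once by the
  least-squares fit and once by the parameter regressor, and the signed
  percentage error of tau is recorded.

* **Test 2 (full chains)** scores the complete pipelines -- classifier +
  regressor (ML), fit + AICc, fit + Akaike-weight averaging, and fit +
  F-test -- including every misclassification they make.

Per chain and N the report carries the classification accuracy and the
Delta-tau distribution summary (median, quartiles with the
linear-interpolation convention, interquartile width, and the maximum
error range, i.e. the [min, max] of Delta-tau).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fitting import fit_both, fit_model
from .ml import TACModelChain
from .models import BEF, MEF, tau as tau_of
from .selection import (
    NotApplicableError,
    aicc_select,
    f_test_select,
    min_points,
    tau_aicc_weighted,
)
from .simulate import DatasetSpec, TACDataset, generate_dataset

__all__ = [
    "ExperimentConfig",
    "DeltaTauSummary",
    "BenchmarkReport",
    "classification_accuracy",
    "delta_tau",
    "summarize_deltas",
    "train_chain",
    "run_test1_known_class",
    "run_test2_full_chains",
    "derive_seed",
]

CHAINS_TEST1 = ("fit_only", "ml2_only")
CHAINS_TEST2 = ("fit_aicc", "fit_aiccw", "fit_ftest", "ml1_ml2")

_ROLE_CODES = {"train": 0, "test": 1, "ml": 2, "cv": 3}


def derive_seed(master_seed: int, n_points: int, role: str) -> int:
    """Deterministic per-(N, role) child seed from one master seed.

    Stream splitting uses :class:`numpy.random.SeedSequence` spawn keys, so
    every dataset and every trained model in an experiment draws from an
    independent, reproducible stream.  The result fits in 31 bits so it can
    seed scikit-learn estimators directly.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(n_points, _ROLE_CODES[role]))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one benchmark experiment.

    Defaults are the full study conditions: ten values of N spanning 4-20,
    training sets of 5000 + 5000 noise-free curves, test sets of
    1000 + 1000 curves with 5 % relative noise, F-test significance 0.05.
    ``regressor_params`` forwards size knobs to the parameter regressor
    (e.g. smaller ensembles for quick runs).
    """

    n_set: Tuple[int, ...] = (4, 5, 6, 8, 10, 12, 14, 16, 18, 20)
    train_me: int = 5000
    train_be: int = 5000
    test_me: int = 1000
    test_be: int = 1000
    noise: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    coupling: str = "component"
    regressor_params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_set or min(self.n_set) < 4:
            raise ValueError("n_set values must be >= 4")
        if min(self.train_me, self.train_be, self.test_me, self.test_be) <= 0:
            raise ValueError("all set sizes must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def train_spec(self, n_points: int) -> DatasetSpec:
        return DatasetSpec(
            n_points, self.train_me, self.train_be, 0.0,
            derive_seed(self.seed, n_points, "train"), self.coupling,
        )

    def test_spec(self, n_points: int) -> DatasetSpec:
        return DatasetSpec(
            n_points, self.test_me, self.test_be, self.noise,
            derive_seed(self.seed, n_points, "test"), self.coupling,
        )


@dataclass(frozen=True)
class DeltaTauSummary:
    """Distribution summary of signed percentage tau errors for one chain."""

    n_points: int
    chain: str
    median: float
    q1: float
    q3: float
    iqr_width: float
    mer: Tuple[float, float]
    n_curves: int

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must bracket the median")
        if self.mer[0] > self.q1 or self.mer[1] < self.q3:
            raise ValueError("MER must contain the interquartile range")


@dataclass
class BenchmarkReport:
    """Per-N, per-chain benchmark results plus the configuration echo."""

    config: ExperimentConfig
    summaries: List[DeltaTauSummary] = field(default_factory=list)
    accuracies: Dict[Tuple[int, str], float] = field(default_factory=dict)
    convergence_failures: Dict[int, int] = field(default_factory=dict)

    def summary(self, n_points: int, chain: str) -> DeltaTauSummary:
        for s in self.summaries:
            if s.n_points == n_points and s.chain == chain:
                return s
        raise KeyError((n_points, chain))

    def to_dict(self) -> Dict:
        return {
            "config": asdict(self.config),
            "summaries": [asdict(s) for s in self.summaries],
            "accuracies": {f"{n}:{m}": v for (n, m), v in self.accuracies.items()},
            "convergence_failures": dict(self.convergence_failures),
        }


def classification_accuracy(predicted, truth) -> float:
    """Percentage of curves assigned their generating model class.

    With balanced classes this equals the mean of the per-class recalls.
    """
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have equal length")
    return 100.0 * float(np.mean(p == t))


def delta_tau(tau_est, tau_true):
    """Signed percentage difference 100 * (est - true) / true.

    Negative values are underestimates.  Scalar in, scalar out.
    """
    est = np.asarray(tau_est, dtype=float)
    true = np.asarray(tau_true, dtype=float)
    if np.any(true <= 0):
        raise ValueError("tau_true must be > 0")
    out = 100.0 * (est - true) / true
    return float(out) if out.ndim == 0 else out


def summarize_deltas(
    deltas: Sequence[float], n_points: int = 0, chain: str = ""
) -> DeltaTauSummary:
    """Median, linear-interpolation quartiles, IQR width and MER of a
    Delta-tau sample."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("cannot summarize an empty Delta-tau sample")
    q1, med, q3 = np.percentile(d, [25.0, 50.0, 75.0])
    return DeltaTauSummary(
        n_points=n_points,
        chain=chain,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr_width=float(q3 - q1),
        mer=(float(d.min()), float(d.max())),
        n_curves=int(d.size),
    )


def train_chain(config: ExperimentConfig, n_points: int) -> TACModelChain:
    """Generate the noise-free training set for one N and train its chain."""
    train = generate_dataset(config.train_spec(n_points))
    chain = TACModelChain.from_config(
        n_points,
        random_state=derive_seed(config.seed, n_points, "ml"),
        **config.regressor_params,
    )
    return chain.fit(train)


def _tau_from_matrix(m: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nansum(m[:, 0::2] / m[:, 1::2], axis=1)


@dataclass
class _FittedTestSet:
    """Both-model fits of every curve in one test set (shared by chains)."""

    ss_me: np.ndarray
    ss_be: np.ndarray
    tau_me: np.ndarray
    tau_be: np.ndarray
    fits_me: list
    fits_be: list
    n_failures: int


def _fit_test_set(test: TACDataset) -> _FittedTestSet:
    n = len(test)
    ss_me = np.empty(n)
    ss_be = np.empty(n)
    tau_me = np.empty(n)
    tau_be = np.empty(n)
    fits_me, fits_be = [], []
    failures = 0
    for i in range(n):
        fm, fb = fit_both(test[i])
        fits_me.append(fm)
        fits_be.append(fb)
        ss_me[i], ss_be[i] = fm.ss, fb.ss
        tau_me[i], tau_be[i] = tau_of(fm.params), tau_of(fb.params)
        failures += (not fm.converged) + (not fb.converged)
    return _FittedTestSet(ss_me, ss_be, tau_me, tau_be, fits_me, fits_be, failures)


def run_test1_known_class(
    config: ExperimentConfig,
    chains: Optional[Dict[int, TACModelChain]] = None,
) -> BenchmarkReport:
    """Best-case estimation test: the true model class is supplied.

    For every N the noisy test curves are processed twice -- fitted with
    their generating model family (``fit_only``) and passed through the
    parameter regressor with the true class indicator (``ml2_only``) --
    and the Delta-tau distributions are summarised.
    """
    report = BenchmarkReport(config=config)
    for n_pts in config.n_set:
        chain = (chains or {}).get(n_pts) or train_chain(config, n_pts)
        test = generate_dataset(config.test_spec(n_pts))
        kinds = np.array([str(k) for k in test.kinds])
        tau_true = test.true_tau()

        if n_pts >= 5:  # at N=4 the BEf fit has no residual degrees of freedom
            tau_fit = np.empty(len(test))
            for i in range(len(test)):
                fit = fit_model(test[i], kinds[i])
                tau_fit[i] = tau_of(fit.params)
            report.summaries.append(
                summarize_deltas(delta_tau(tau_fit, tau_true), n_pts, "fit_only")
            )

        pred = chain.predict_parameters_batch(test, kinds)
        tau_ml = _tau_from_matrix(pred)
        report.summaries.append(
            summarize_deltas(delta_tau(tau_ml, tau_true), n_pts, "ml2_only")
        )
    return report


def run_test2_full_chains(
    config: ExperimentConfig,
    chains: Optional[Dict[int, TACModelChain]] = None,
) -> BenchmarkReport:
    """Full-chain test: model selection errors propagate into tau.

    Chains below their applicability threshold (F-test N >= 5, AICc and
    AICc-weighted averaging N >= 6) are skipped at that N rather than
    defaulted.  The AICc-weighted chain averages tau with the Akaike
    weights; its classification accuracy is scored by the larger weight,
    which coincides with the AICc choice.
    """
    report = BenchmarkReport(config=config)
    for n_pts in config.n_set:
        chain = (chains or {}).get(n_pts) or train_chain(config, n_pts)
        test = generate_dataset(config.test_spec(n_pts))
        kinds = np.array([str(k) for k in test.kinds])
        tau_true = test.true_tau()
        fitted = None
        if n_pts >= min_points("FTest"):  # below N=5 no analytic chain applies
            fitted = _fit_test_set(test)
            report.convergence_failures[n_pts] = fitted.n_failures

        # ML chain: classify, then regress with the predicted class
        pred_cls = chain.classify_batch(test)
        pred = chain.predict_parameters_batch(test, pred_cls)
        tau_ml = _tau_from_matrix(pred)
        report.accuracies[(n_pts, "ml1_ml2")] = classification_accuracy(pred_cls, kinds)
        report.summaries.append(
            summarize_deltas(delta_tau(tau_ml, tau_true), n_pts, "ml1_ml2")
        )

        # analytic chains from the shared fits
        if n_pts >= min_points("FTest"):
            choice = np.empty(len(test), dtype=object)
            for i in range(len(test)):
                choice[i] = f_test_select(
                    fitted.fits_me[i], fitted.fits_be[i], config.alpha
                ).chosen
            tau_sel = np.where(choice == BEF, fitted.tau_be, fitted.tau_me)
            report.accuracies[(n_pts, "fit_ftest")] = classification_accuracy(choice, kinds)
            report.summaries.append(
                summarize_deltas(delta_tau(tau_sel, tau_true), n_pts, "fit_ftest")
            )

        if n_pts >= min_points("AICc"):
            choice = np.empty(len(test), dtype=object)
            tau_w = np.empty(len(test))
            for i in range(len(test)):
                sel = aicc_select(fitted.fits_me[i], fitted.fits_be[i])
                choice[i] = sel.chosen
                tau_w[i] = tau_aicc_weighted(
                    fitted.tau_me[i], fitted.tau_be[i], sel.w_me, sel.w_be
                )
            tau_sel = np.where(choice == BEF, fitted.tau_be, fitted.tau_me)
            ca = classification_accuracy(choice, kinds)
            report.accuracies[(n_pts, "fit_aicc")] = ca
            report.accuracies[(n_pts, "fit_aiccw")] = ca
            report.summaries.append(
                summarize_deltas(delta_tau(tau_sel, tau_true), n_pts, "fit_aicc")
            )
            report.summaries.append(
                summarize_deltas(delta_tau(tau_w, tau_true), n_pts, "fit_aiccw")
            )
    return report
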