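"""Machine-learning route to model selection and parameter prediction.

Two supervised systems, both trained per number of curve points N on
noise-free synthetic curves and applied to noisy curves:

* :class:`SoftVotingTACClassifier` -- a soft-voting ensemble of two
  logistic regressions that assigns a curve to the mono- or bi-exponential
  family from its 2N raw (t, FIA) coordinates;
* :class:`BoostedParameterRegressor` -- one AdaBoost ensemble of gradient
  boosted regression trees per biokinetic parameter, consuming the 2N
  coordinates plus a model-class indicator (2N + 1 features) and emitting
  the amplitude/rate estimates from which tau follows analytically.

Both follow the scikit-learn estimator contract (``fit`` / ``predict`` /
``get_params``) and compose with scikit-learn model selection utilities.
:class:`TACModelChain` bundles a classifier and the two per-class
regressor banks for one N, with persistence.

The feature layout is fixed: ``[t_1..t_N, fia_1..fia_N]`` and, for the
regressor, the class indicator (0 = MEf, 1 = BEf) appended last.  No
feature scaling is applied; tree ensembles are scale-invariant and the
logistic voters are trained on the raw coordinates (convergence at the
configured iteration caps is reported by scikit-learn's usual warnings).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import joblib
import numpy as np
from sklearn import __version__ as _sklearn_version
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    VotingClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.multioutput import MultiOutputRegressor
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .models import BEF, MEF, ExponentialParams
from .selection import ModelSelection
from .simulate import TACDataset, TACPoints

__all__ = [
    "build_features",
    "dataset_features",
    "SoftVotingTACClassifier",
    "BoostedParameterRegressor",
    "TACModelChain",
    "cross_validate_classifier",
]

_CLASS_CODE = {MEF: 0.0, BEF: 1.0}


def build_features(tac: TACPoints, model_class: Optional[str] = None) -> np.ndarray:
    """Feature vector of one curve: [t_1..t_N, fia_1..fia_N (, class)].

    The class indicator (0 = MEf, 1 = BEf) is appended only when
    ``model_class`` is given, yielding 2N + 1 features instead of 2N.
    """
    base = np.concatenate([tac.times, tac.fia])
    if model_class is None:
        return base
    return np.concatenate([base, [_CLASS_CODE[model_class]]])


def dataset_features(
    dataset: TACDataset, with_class: bool = False, class_override=None
) -> np.ndarray:
    """Feature matrix for a whole dataset (vectorised ``build_features``)."""
    n = len(dataset)
    tmat = np.tile(dataset.times, (n, 1))
    cols = [tmat, dataset.fia]
    if with_class:
        if class_override is None:
            codes = np.array([_CLASS_CODE[str(k)] for k in dataset.kinds])
        else:
            codes = np.asarray(
                [_CLASS_CODE[k] if isinstance(k, str) else float(k) for k in np.atleast_1d(class_override)]
            )
            if codes.size == 1:
                codes = np.full(n, codes[0])
        cols.append(codes[:, None])
    return np.hstack(cols)


class SoftVotingTACClassifier(ClassifierMixin, BaseEstimator):
    """Soft-voting ensemble of two logistic regressions.

    The two voters share the model but differ in optimisation
    configuration: the first uses the ``liblinear`` solver with its default
    iteration cap, the second the ``sag`` solver with a large cap.  Their
    predicted class probabilities are averaged and the curve is assigned to
    the bi-exponential class only when its averaged probability exceeds
    0.5; an exact tie goes to the simpler mono-exponential model.

    Parameters
    ----------
    max_iter_liblinear, max_iter_sag : int
        Iteration caps of the two voters.
    random_state : int or None
        Seeds the ``sag`` data shuffling; fixing it makes training
        bit-reproducible.
    """

    def __init__(self, max_iter_liblinear: int = 100, max_iter_sag: int = 10000,
                 random_state: Optional[int] = None):
        self.max_iter_liblinear = max_iter_liblinear
        self.max_iter_sag = max_iter_sag
        self.random_state = random_state

    def _make_ensemble(self) -> VotingClassifier:
        return VotingClassifier(
            estimators=[
                (
                    "liblinear",
                    LogisticRegression(
                        solver="liblinear",
                        max_iter=self.max_iter_liblinear,
                        random_state=self.random_state,
                    ),
                ),
                (
                    "sag",
                    LogisticRegression(
                        solver="sag",
                        max_iter=self.max_iter_sag,
                        random_state=self.random_state,
                    ),
                ),
            ],
            voting="soft",
        )

    def fit(self, X, y) -> "SoftVotingTACClassifier":
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain both model classes")
        self.ensemble_ = self._make_ensemble()
        with warnings.catch_warnings():
            # the sag voter may stop on its iteration cap on raw-scale
            # features; the averaged vote is still well defined
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.ensemble_.fit(X, y)
        self.classes_ = self.ensemble_.le_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "ensemble_")
        X = check_array(X)
        return self.ensemble_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        be_col = int(np.where(self.classes_ == BEF)[0][0])
        return np.where(proba[:, be_col] > 0.5, BEF, MEF)


class BoostedParameterRegressor(RegressorMixin, BaseEstimator):
    """AdaBoost-of-gradient-boosting regressor bank, one ensemble per target.

    Each output (a biokinetic parameter) gets an AdaBoost ensemble whose
    weak learner is a gradient-boosted chain of depth-5 regression trees
    with squared-error loss; the AdaBoost layer combines them with the
    linear boosting loss.  Defaults follow the reference configuration
    (1000 trees per booster, 5 boosters, learning rate 0.1); smaller
    values trade accuracy for training time.
    """

    def __init__(
        self,
        gbr_n_estimators: int = 1000,
        ada_n_estimators: int = 5,
        learning_rate: float = 0.1,
        max_depth: int = 5,
        random_state: Optional[int] = None,
    ):
        self.gbr_n_estimators = gbr_n_estimators
        self.ada_n_estimators = ada_n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def _make_ensemble(self) -> MultiOutputRegressor:
        gbr = GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=self.gbr_n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            random_state=self.random_state,
        )
        ada = AdaBoostRegressor(
            estimator=gbr,
            n_estimators=self.ada_n_estimators,
            learning_rate=self.learning_rate,
            loss="linear",
            random_state=self.random_state,
        )
        return MultiOutputRegressor(ada)

    def fit(self, X, y) -> "BoostedParameterRegressor":
        X, y = check_X_y(X, y, multi_output=True)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        self.model_ = self._make_ensemble()
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.predict(X)


@dataclass
class TACModelChain:
    """Classifier + per-class regressor banks for curves with N points.

    ``fit`` trains all three estimators on one noise-free training
    dataset; ``classify`` and ``predict_parameters`` then accept only
    curves with the same number of points.
    """

    n_points: int
    classifier: SoftVotingTACClassifier = None
    regressor_me: BoostedParameterRegressor = None
    regressor_be: BoostedParameterRegressor = None
    training_meta: Dict = field(default_factory=dict)

    @classmethod
    def from_config(
        cls,
        n_points: int,
        random_state: Optional[int] = None,
        **regressor_params,
    ) -> "TACModelChain":
        return cls(
            n_points=n_points,
            classifier=SoftVotingTACClassifier(random_state=random_state),
            regressor_me=BoostedParameterRegressor(random_state=random_state, **regressor_params),
            regressor_be=BoostedParameterRegressor(random_state=random_state, **regressor_params),
        )

    def _check_n(self, n: int) -> None:
        if n != self.n_points:
            raise ValueError(
                f"chain trained for N={self.n_points} cannot process a curve with N={n}"
            )

    def fit(self, train: TACDataset) -> "TACModelChain":
        self._check_n(train.n_points)
        if train.noisy:
            warnings.warn("training on noisy curves degrades classification accuracy")
        kinds = np.array([str(k) for k in train.kinds])
        X_cls = dataset_features(train)
        self.classifier.fit(X_cls, kinds)
        X_reg = dataset_features(train, with_class=True)
        me_rows = kinds == MEF
        be_rows = kinds == BEF
        if np.isnan(train.truth_matrix[me_rows, :2]).any() or np.isnan(
            train.truth_matrix[be_rows, :4]
        ).any():
            raise ValueError("training dataset must carry truth parameters")
        self.regressor_me.fit(X_reg[me_rows], train.truth_matrix[me_rows, :2])
        self.regressor_be.fit(X_reg[be_rows], train.truth_matrix[be_rows, :4])
        self.training_meta = {
            "n_points": self.n_points,
            "n_me": int(me_rows.sum()),
            "n_be": int(be_rows.sum()),
            "dataset_seed": getattr(train.spec, "seed", None),
            "sklearn_version": _sklearn_version,
        }
        return self

    # -- single-curve interface ------------------------------------------

    def classify(self, tac: TACPoints) -> ModelSelection:
        self._check_n(tac.n)
        proba = self.classifier.predict_proba(build_features(tac)[None, :])[0]
        me_col = int(np.where(self.classifier.classes_ == MEF)[0][0])
        p_me, p_be = float(proba[me_col]), float(1.0 - proba[me_col])
        chosen = BEF if p_be > 0.5 else MEF
        return ModelSelection(chosen=chosen, method="ML", class_probs=(p_me, p_be))

    def predict_parameters(self, tac: TACPoints, model_class: str) -> ExponentialParams:
        self._check_n(tac.n)
        x = build_features(tac, model_class)[None, :]
        reg = self.regressor_me if model_class == MEF else self.regressor_be
        theta = reg.predict(x)[0]
        return ExponentialParams.from_array(model_class, theta)

    # -- batch interface (used by the benchmark) -------------------------

    def classify_batch(self, dataset: TACDataset) -> np.ndarray:
        self._check_n(dataset.n_points)
        return self.classifier.predict(dataset_features(dataset))

    def predict_parameters_batch(
        self, dataset: TACDataset, model_classes: np.ndarray
    ) -> np.ndarray:
        """Predicted parameter matrix (n_curves, 4), MEf rows NaN-padded."""
        self._check_n(dataset.n_points)
        classes = np.asarray(model_classes)
        X = dataset_features(dataset, with_class=True, class_override=classes)
        out = np.full((len(dataset), 4), np.nan)
        me_rows = classes == MEF
        if me_rows.any():
            out[me_rows, :2] = self.regressor_me.predict(X[me_rows])
        if (~me_rows).any():
            pred = self.regressor_be.predict(X[~me_rows])
            swap = pred[:, 1] < pred[:, 3]
            pred[swap] = pred[swap][:, [2, 3, 0, 1]]
            out[~me_rows] = pred
        return out

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        """Persist the chain as ``chain_N<k>.bin`` plus a JSON sidecar."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, d / f"chain_N{self.n_points}.bin")
        with open(d / f"chain_N{self.n_points}.json", "w") as fh:
            json.dump(self.training_meta, fh, indent=2)

    @classmethod
    def load(cls, directory, n_points: int) -> "TACModelChain":
        from pathlib import Path

        return joblib.load(Path(directory) / f"chain_N{n_points}.bin")


def cross_validate_classifier(
    train: TACDataset, seed: int = 0, n_splits: int = 10, test_size: float = 0.2
) -> List[float]:
    """Repeated stratified 80/20 split validation of the classifier.

    Ten independent stratified shuffle splits, each training a fresh
    soft-voting classifier on 80 % of the noise-free training curves and
    scoring accuracy on the held-out 20 %.  Returns the per-split
    accuracies as fractions in [0, 1].
    """
    kinds = np.array([str(k) for k in train.kinds])
    X = dataset_features(train)
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_size, random_state=seed
    )
    accs = []
    for tr_idx, te_idx in splitter.split(X, kinds):
        clf = SoftVotingTACClassifier(random_state=seed)
        clf.fit(X[tr_idx], kinds[tr_idx])
        accs.append(float(np.mean(clf.predict(X[te_idx]) == kinds[te_idx])))
    return accs
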