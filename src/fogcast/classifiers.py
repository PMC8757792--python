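"""The three freeze-forecast classifiers and their vote combination.

The benchmark Gaussian naive Bayes is implemented here from first
principles: class priors are label relative frequencies, per-feature
class-conditional densities are Gaussians with maximum-likelihood
(biased) mean/variance estimates, and prediction is the MAP rule
``argmax_y  P(y) * prod_i P(x_i | y)`` evaluated in log space with a
variance floor.  The random forest (max depth 200, freeze class weighted
100:1) and the multilayer perceptron (5 hidden layers of 100 units,
L-BFGS solver) are scikit-learn estimators at those configurations.

The three members are wrapped in a statsmodels-style model/results
pair: :class:`EnsembleForecaster` holds the training data and
configuration, its :meth:`~EnsembleForecaster.fit` returns an
:class:`EnsembleForecasterResults` that predicts and combines votes.
The vote rule is the sensitivity/specificity dial: *minority* fires
when any member predicts a freeze (fewest misses, most false alarms),
*majority* requires 2 of 3.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .windowing import WindowedDataset

__all__ = [
    "SingleClassError",
    "GaussianNBModel",
    "fit_gaussian_nb",
    "predict_gaussian_nb",
    "EnsembleConfig",
    "EnsembleForecaster",
    "EnsembleForecasterResults",
    "fit_ensemble",
    "combine_votes",
    "VOTE_RULES",
]

VOTE_RULES = ("minority", "majority", "nb_only", "rf_only", "nn_only")

MEMBERS = ("nb", "rf", "nn")


class SingleClassError(ValueError):
    """Training data contains only one class; the caller decides the fallback."""


# ---------------------------------------------------------------------------
# Gaussian naive Bayes (from scratch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianNBModel:
    """MLE-fitted Gaussian naive Bayes parameters for classes {0, 1}.

    ``means``/``variances`` have shape (2, n_features); row y holds the
    per-feature mean and biased sample variance of class y.  ``priors``
    are the class relative frequencies.  Variances are floored at
    ``variance_floor`` so constant features keep finite log-likelihoods.
    """

    priors: np.ndarray  # (2,)
    means: np.ndarray  # (2, n_features)
    variances: np.ndarray  # (2, n_features)
    variance_floor: float

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0, atol=1e-12):
            raise ValueError("priors must sum to 1")
        if (self.variances < self.variance_floor - 1e-300).any():
            raise ValueError("variances below floor")

    @property
    def n_features(self) -> int:
        return int(self.means.shape[1])


def fit_gaussian_nb(
    dataset: WindowedDataset | tuple[np.ndarray, np.ndarray],
    *,
    variance_floor_scale: float = 1e-9,
) -> GaussianNBModel:
    """Fit the Gaussian NB by maximum likelihood.

    Per class y: prior = relative frequency; per feature i: mean and
    biased variance of that class's rows.  The variance floor is
    ``variance_floor_scale`` times the mean overall feature variance
    (with an absolute fallback of 1e-12 when the data are constant).

    Raises
    ------
    SingleClassError
        If the dataset does not contain both classes.
    """
    if isinstance(dataset, WindowedDataset):
        X, y = dataset.inputs, dataset.labels
    else:
        X, y = dataset
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one label per row")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise SingleClassError(f"need both classes {{0,1}}, got {classes.tolist()}")

    floor = max(variance_floor_scale * float(X.var(axis=0).mean()), 1e-12)
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    means = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.stack([X[y == c].var(axis=0) for c in (0, 1)])  # biased MLE
    variances = np.maximum(variances, floor)
    return GaussianNBModel(priors=priors, means=means, variances=variances,
                           variance_floor=floor)


def nb_log_joint(model: GaussianNBModel, X: np.ndarray) -> np.ndarray:
    """log P(y) + sum_i log N(x_i; mu_yi, var_yi) for y in {0, 1}; shape (n, 2)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input width {X.shape[1]} does not match model ({model.n_features})"
        )
    out = np.empty((X.shape[0], 2))
    for c in (0, 1):
        mu, var = model.means[c], model.variances[c]
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)
        out[:, c] = np.log(model.priors[c]) + ll
    return out


def predict_gaussian_nb(model: GaussianNBModel, X: np.ndarray) -> np.ndarray:
    """MAP labels; ties break toward 0 (no freeze)."""
    joint = nb_log_joint(model, X)
    return (joint[:, 1] > joint[:, 0]).astype(int)


# ---------------------------------------------------------------------------
# Vote combination
# ---------------------------------------------------------------------------

def combine_votes(member_predictions, rule: str) -> np.ndarray:
    """Combine the three members' {0,1} votes.

    minority: 1 iff at least one member votes 1 (maximum sensitivity);
    majority: 1 iff at least two of three vote 1; the ``*_only`` rules
    pass a single member through.
    """
    if rule not in VOTE_RULES:
        raise ValueError(f"unknown vote rule {rule!r}; choose from {VOTE_RULES}")
    votes = {m: np.atleast_1d(np.asarray(v, dtype=int))
             for m, v in zip(MEMBERS, member_predictions)}
    lengths = {v.size for v in votes.values()}
    if len(lengths) != 1:
        raise ValueError("member prediction lengths differ")
    if rule.endswith("_only"):
        return votes[rule[:-5]]
    total = sum(votes.values())
    return (total >= (1 if rule == "minority" else 2)).astype(int)


# ---------------------------------------------------------------------------
# Ensemble model / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleConfig:
    """Hyper-parameters of the three members.

    The RF depth/class-weight and the NN topology/solver follow the
    pipeline's reference configuration; the remaining knobs (tree count,
    NN activation, iteration cap, L2 penalty) are this package's own
    defaults and are configurable.
    """

    rf_n_estimators: int = 100
    rf_max_depth: int = 200
    rf_class_weight_true: float = 100.0
    nn_hidden_layers: int = 5
    nn_hidden_units: int = 100
    nn_solver: str = "lbfgs"
    nn_activation: str = "relu"
    nn_max_iter: int = 500
    nn_alpha: float = 1e-4
    variance_floor_scale: float = 1e-9
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _fit_member(name: str, X: np.ndarray, y: np.ndarray, config: EnsembleConfig):
    """Fit one member classifier on (X, y)."""
    if name == "nb":
        return fit_gaussian_nb((X, y),
                               variance_floor_scale=config.variance_floor_scale)
    if name == "rf":
        rf = RandomForestClassifier(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            class_weight={0: 1.0, 1: config.rf_class_weight_true},
            random_state=config.seed,
            n_jobs=1,
        )
        return rf.fit(X, y)
    if name == "nn":
        nn = MLPClassifier(
            hidden_layer_sizes=(config.nn_hidden_units,) * config.nn_hidden_layers,
            solver=config.nn_solver,
            activation=config.nn_activation,
            max_iter=config.nn_max_iter,
            alpha=config.nn_alpha,
            random_state=config.seed,
        )
        return nn.fit(X, y)
    raise ValueError(f"unknown member {name!r}")


def predict_member(name: str, model, X: np.ndarray) -> np.ndarray:
    if name == "nb":
        return predict_gaussian_nb(model, X)
    return np.asarray(model.predict(X), dtype=int)


class EnsembleForecaster:
    """Three-member freeze-forecast ensemble, statsmodels style.

    Parameters
    ----------
    dataset : WindowedDataset
        Training windows; must contain both classes.
    config : EnsembleConfig
        Member hyper-parameters and the shared seed.

    Examples
    --------
    >>> model = EnsembleForecaster(train_windows)          # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> votes = res.predict(test_windows.inputs, rule="minority")  # doctest: +SKIP
    """

    def __init__(self, dataset: WindowedDataset, config: EnsembleConfig | None = None):
        if len(np.unique(dataset.labels)) < 2:
            raise SingleClassError("training windows contain a single class")
        self.dataset = dataset
        self.config = config or EnsembleConfig()

    def fit(self, members=MEMBERS) -> "EnsembleForecasterResults":
        """Train the requested members on identical rows."""
        X, y = self.dataset.inputs, self.dataset.labels
        fitted = {m: _fit_member(m, X, y, self.config) for m in members}
        return EnsembleForecasterResults(
            model=self,
            members=fitted,
            n_train=len(self.dataset),
            train_subjects=tuple(sorted(set(self.dataset.subjects.tolist()))),
        )


class EnsembleForecasterResults:
    """Fitted ensemble: member models plus training provenance."""

    def __init__(self, model, members: dict, n_train: int, train_subjects: tuple):
        self.model = model
        self.members = members
        self.n_train = n_train
        self.train_subjects = train_subjects

    @property
    def config(self) -> EnsembleConfig:
        return self.model.config

    @property
    def il(self) -> int:
        return self.model.dataset.params.IL

    def member_predictions(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Per-member {0,1} votes, keyed nb/rf/nn (fitted members only)."""
        return {m: predict_member(m, est, X) for m, est in self.members.items()}

    def predict(self, X: np.ndarray, rule: str = "minority") -> np.ndarray:
        """Combined {0,1} prediction under the given vote rule."""
        if rule.endswith("_only"):
            name = rule[:-5]
            return predict_member(name, self.members[name], X)
        if set(MEMBERS) - set(self.members):
            raise ValueError(
                f"rule {rule!r} needs all three members; fitted: {list(self.members)}"
            )
        votes = self.member_predictions(X)
        return combine_votes([votes[m] for m in MEMBERS], rule)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Freeze-forecast ensemble",
            "=" * 40,
            f"members fitted:     {', '.join(self.members)}",
            f"training windows:   {self.n_train}",
            f"training subjects:  {', '.join(self.train_subjects)}",
            f"input length (IL):  {self.il} cs",
            f"RF: {cfg.rf_n_estimators} trees, depth {cfg.rf_max_depth}, "
            f"class weight 1:{cfg.rf_class_weight_true:g}",
            f"NN: {cfg.nn_hidden_layers} x {cfg.nn_hidden_units} units, "
            f"{cfg.nn_solver}, {cfg.nn_activation}",
            f"seed: {cfg.seed}",
        ]
        return "\n".join(lines)


def fit_ensemble(
    dataset: WindowedDataset,
    config: EnsembleConfig | None = None,
    members=MEMBERS,
) -> EnsembleForecasterResults:
    """Convenience wrapper: ``EnsembleForecaster(dataset, config).fit(members)``."""
    return EnsembleForecaster(dataset, config).fit(members)
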