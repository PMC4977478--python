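"""scikit-learn-style estimator wrapping the softplus/dropout network.

``EnhancerMLP`` composes with sklearn pipelines and model selection: it
implements fit/predict/decision_function, clones cleanly through
get_params/set_params, and exposes fitted state through trailing-underscore
attributes.  ``decision_function`` returns the network's raw score (the
quantity thresholded into enhancer calls); ``feature_importances_`` exposes
the connection-weight attribution of the trained network.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .importance import importance_scores
from .network import TrainConfig, predict as _predict_net, train_network


class EnhancerMLP(ClassifierMixin, BaseEstimator):
    """Feedforward enhancer classifier with softplus units and dropout SGD.

    Parameters
    ----------
    hidden_sizes : tuple of int, default (600, 500, 400)
        Hidden-layer widths.
    epochs, batch_size, learning_rate, momentum, dropout_rate
        Mini-batch SGD settings; squared-error loss on 1/0 labels, dropout on
        hidden layers with inverted scaling.
    output_activation : {"softplus", "linear"}
        Activation of the single output unit.
    standardize : bool, default True
        Z-score features on fit (mean/scale reused at prediction); keeps SGD
        well-conditioned when RPKM scales vary between libraries.
    threshold : float, default 0.5
        Score cut used by :meth:`predict`; label 1 iff score > threshold.
    random_state : int, default 0
        Seeds initialization, shuffling and dropout masks.

    Attributes
    ----------
    network_ : NetworkParams
        Trained weights and biases.
    loss_curve_ : list of float
        Per-epoch training mean squared error.
    feature_importances_ : ndarray
        Per-feature connection-weight importance scores of the trained net.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (600, 500, 400),
        epochs: int = 5,
        batch_size: int = 100,
        learning_rate: float = 0.01,
        momentum: float = 0.0,
        dropout_rate: float = 0.5,
        output_activation: str = "softplus",
        standardize: bool = True,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout_rate = dropout_rate
        self.output_activation = output_activation
        self.standardize = standardize
        self.threshold = threshold
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            dropout_rate=self.dropout_rate,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            seed=self.random_state,
            hidden_sizes=tuple(self.hidden_sizes),
            output_activation=self.output_activation,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = np.asarray(y)
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("EnhancerMLP expects binary 0/1 labels")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
            X = (X - self.mean_) / self.scale_
        self.network_, self.loss_curve_ = train_network(
            X, y.astype(float), self._train_config()
        )
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            return (X - self.mean_) / self.scale_
        return X

    def decision_function(self, X) -> np.ndarray:
        """Raw network scores (no dropout at prediction time)."""
        check_is_fitted(self, "network_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        return _predict_net(self.network_, self._transform(X))

    def predict(self, X) -> np.ndarray:
        """Enhancer labels: 1 iff raw score strictly exceeds ``threshold``."""
        return (self.decision_function(X) > self.threshold).astype(int)

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "network_")
        return importance_scores(self.network_).per_feature
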