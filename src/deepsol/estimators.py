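"""scikit-learn-style regressors wrapping the fingerprint networks.

Both estimators follow the sklearn contract (``get_params``/``set_params``,
``fit``/``predict``/``score``, trailing-underscore fitted attributes), so
they compose with pipelines and model-selection utilities.  ``fit`` consumes
an (n_samples, n_bits) 0/1 fingerprint matrix and a logS target vector.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .architectures import DNNSpec, ResNetSpec, build_model
from .training import TrainConfig, fit_network

__all__ = ["ResNetRegressor", "DNNRegressor"]


class _BaseNetRegressor(RegressorMixin, BaseEstimator):
    def _make_spec(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def _train_config(self) -> TrainConfig:
        seed = self.random_state if self.random_state is not None else 0
        return TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            l2_lambda=None,  # taken from the architecture spec
            seed=int(seed),
            loss=self.loss,
            validation_fraction=self.validation_fraction,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float32, y_numeric=True)
        spec = self._make_spec()
        config = self._train_config()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        net = build_model(spec, input_length=X.shape[1], rng=rng)
        history = fit_network(net, X, y, config)
        self.network_ = net
        self.spec_ = spec
        self.history_ = history
        self.layer_audit_ = net.layer_audit
        self.n_parameters_ = net.n_parameters
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = len(history)
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=np.float32)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, but the model was fit with {self.n_features_in_}"
            )
        return self.network_.forward(X, training=False).astype(float)


class ResNetRegressor(_BaseNetRegressor):
    """Residual 1D-CNN logS regressor on binary substructure fingerprints.

    Parameters
    ----------
    n_layers : headline depth N — N-1 convolutions plus 1 fully connected
        output layer; (N-2)/2 residual blocks split equally over the channel
        stages, so N must satisfy that arithmetic (8, 14, 20 and 26 all do
        with the default three stages).
    stage_channels : channel count per stage; the sequence length is halved
        (``downsample_stride``) at each stage transition.
    loss : 'neg_r2' trains by the batchwise negative coefficient of
        determination; 'mse' by mean squared error.
    """

    def __init__(self, n_layers: int = 20, stage_channels: tuple = (9, 18, 36),
                 stem_kernel: int = 7, block_kernel: int = 3,
                 downsample_stride: int = 2, activation: str = "relu",
                 l2: float = 1e-4, batch_norm: bool = True, init_scale: float = 1.0,
                 optimizer: str = "adam", learning_rate: float = 1e-3,
                 batch_size: int = 64, max_epochs: int = 200,
                 early_stop_patience: int = 20, validation_fraction: float = 0.1,
                 loss: str = "neg_r2", random_state: int | None = None):
        self.n_layers = n_layers
        self.stage_channels = stage_channels
        self.stem_kernel = stem_kernel
        self.block_kernel = block_kernel
        self.downsample_stride = downsample_stride
        self.activation = activation
        self.l2 = l2
        self.batch_norm = batch_norm
        self.init_scale = init_scale
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.loss = loss
        self.random_state = random_state

    def _make_spec(self) -> ResNetSpec:
        return ResNetSpec(
            n_param_layers=self.n_layers,
            stage_channels=tuple(self.stage_channels),
            stem_kernel=self.stem_kernel,
            block_kernel=self.block_kernel,
            downsample_stride=self.downsample_stride,
            activation=self.activation,
            l2_lambda=self.l2,
            use_batch_norm=self.batch_norm,
            init_scale=self.init_scale,
        )


class DNNRegressor(_BaseNetRegressor):
    """Fully connected baseline logS regressor ("shallow-net").

    The default hidden sizes (512, 1024, 2048, 4096) with L2 0.001 and
    dropout 0.5 reproduce the reference 4-hidden-layer baseline; pass
    ``hidden_sizes=(512,)`` for the 1-layer variant.
    """

    def __init__(self, hidden_sizes: tuple = (512, 1024, 2048, 4096),
                 l2: float = 0.001, dropout: float = 0.5, activation: str = "relu",
                 init_scale: float = 1.0, optimizer: str = "adam",
                 learning_rate: float = 1e-3, batch_size: int = 64,
                 max_epochs: int = 200, early_stop_patience: int = 20,
                 validation_fraction: float = 0.1, loss: str = "neg_r2",
                 random_state: int | None = None):
        self.hidden_sizes = hidden_sizes
        self.l2 = l2
        self.dropout = dropout
        self.activation = activation
        self.init_scale = init_scale
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.loss = loss
        self.random_state = random_state

    def _make_spec(self) -> DNNSpec:
        return DNNSpec(
            hidden_sizes=tuple(self.hidden_sizes),
            l2_lambda=self.l2,
            dropout_rate=self.dropout,
            activation=self.activation,
            init_scale=self.init_scale,
        )
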