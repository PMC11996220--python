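"""Pathway-constrained multimodal classifier and its dense baseline.

The constrained model feeds per-gene SNP aggregates and gene expression
through two *frozen* sparse subnetworks whose layer weights are exactly the
0/1 connectivity masks of a gene -> pathway -> pathway hierarchy.  The
subnetwork tops are concatenated with the clinical block and passed through
a trainable head: batch normalisation -> dense(19, linear, L2) ->
dropout(0.597) -> dense(8, ReLU, L2) -> dense(3, softmax).  Training uses
Adam on categorical cross-entropy with a staircase-decayed learning rate
(0.008 x 0.96^floor(t/17)), batch size 32, at most 120 epochs, and early
stopping on validation loss with best-weight restoration.

Both classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba``, fitted attributes with a trailing
underscore) and accept the concatenated feature matrix
``[snp genes | expression genes | clinical]``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._nn import BatchNorm, Dense, Dropout, MultimodalNet, train_network
from .cohort import CLASS_CODES, CLASS_ORDER
from .hierarchy import MaskStack
from .metrics import MetricsReport, evaluate_predictions

__all__ = [
    "ModelConfig",
    "ConstrainedPathwayClassifier",
    "DenseBaselineClassifier",
    "count_parameters",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters with their defaults.

    Defaults follow the published configuration: head widths 19 (linear)
    and 8 (ReLU), dropout 0.597 between them, L2 kernel regularisation,
    initial learning rate 0.008 decaying by 0.96 every 17 optimiser steps
    (staircase), batch size 32, at most 120 epochs, early stopping with
    patience 10.  ``subnetwork_activation`` is identity by default so a
    pathway node is the plain signed sum of its constrained inputs.
    """

    depth: int = 3
    subnetwork_activation: str = "identity"
    hidden1_size: int = 19
    hidden2_size: int = 8
    dropout_rate: float = 0.597
    l2: float = 0.01
    learning_rate: float = 0.008
    decay_rate: float = 0.96
    decay_steps: int = 17
    batch_size: int = 32
    max_epochs: int = 120
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


class _BaseTriClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing for the constrained and dense models."""

    def _encode_y(self, y) -> np.ndarray:
        arr = np.asarray(y)
        if arr.dtype.kind in "iu":
            return arr.astype(int)
        return np.array([CLASS_CODES[v] for v in arr])

    def _onehot(self, codes: np.ndarray) -> np.ndarray:
        out = np.zeros((len(codes), 3))
        out[np.arange(len(codes)), codes] = 1.0
        return out

    def fit(self, X, y, validation_data=None):
        """Train on ``X`` (concatenated [snp | expression | clinical]).

        ``validation_data=(X_val, y_val)`` drives early stopping; without
        it a stratified 20% carve-out of the training rows is used.
        """
        X = np.asarray(X, dtype=float)
        codes = self._encode_y(y)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(X.shape[1], rng)
        if validation_data is not None:
            X_val = np.asarray(validation_data[0], dtype=float)
            y_val = self._encode_y(validation_data[1])
        elif self.validation_fraction and len(X) >= 15:
            X, X_val, codes, y_val = train_test_split(
                X, codes, test_size=self.validation_fraction,
                stratify=codes, random_state=int(rng.integers(2**31 - 1)),
            )
        else:
            X_val = y_val = None
        self.history_ = train_network(
            self.net_, X, self._onehot(codes),
            None if X_val is None else X_val,
            None if X_val is None else self._onehot(y_val),
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, lr0=self.learning_rate,
            decay_rate=self.decay_rate, decay_steps=self.decay_steps,
            rng=rng,
        )
        self.classes_ = np.array(CLASS_ORDER)
        counts = count_parameters(self)
        self.n_trainable_ = counts["trainable"]
        self.n_non_trainable_ = counts["non_trainable"]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_codes(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, X, y) -> MetricsReport:
        """Score the fitted model; see :func:`~pathwaynet.metrics.evaluate_predictions`."""
        return evaluate_predictions(self._encode_y(y), self.predict_proba(X))

    # -- architecture helpers ----------------------------------------------
    def _slices(self, n_features: int) -> dict[str, slice]:
        n1 = self.mask_snp.n_genes
        n2 = self.mask_expr.n_genes
        n_clin = n_features - n1 - n2
        if n_clin < 1:
            raise ValueError(
                f"X has {n_features} columns but masks expect {n1}+{n2} gene columns plus >=1 clinical"
            )
        return {
            "snp": slice(0, n1),
            "expression": slice(n1, n1 + n2),
            "clinical": slice(n1 + n2, n_features),
        }

    def _head(self, concat_width: int, rng: np.random.Generator) -> list:
        return [
            BatchNorm(concat_width),
            Dense(concat_width, self.hidden1_size, "linear", l2=self.l2, rng=rng),
            Dropout(self.dropout_rate),
            Dense(self.hidden1_size, self.hidden2_size, "relu", l2=self.l2, rng=rng),
            Dense(self.hidden2_size, 3, "linear", rng=rng),
        ]


class ConstrainedPathwayClassifier(_BaseTriClassifier):
    """CN/MCI/AD classifier with frozen, mask-constrained omics subnetworks.

    Parameters
    ----------
    mask_snp, mask_expr : MaskStack
        Layered 0/1 connectivity for the SNP-aggregate and expression
        subnetworks; the masks *are* the (non-trainable) weights.
    subnetwork_activation : {"identity", "tanh"}
        Identity makes a pathway node the signed sum of its inputs, so the
        subnetwork forward pass is the plain masked matrix product.

    Remaining parameters mirror :class:`ModelConfig`.
    """

    def __init__(self, mask_snp: MaskStack = None, mask_expr: MaskStack = None,
                 subnetwork_activation: str = "identity",
                 hidden1_size: int = 19, hidden2_size: int = 8,
                 dropout_rate: float = 0.597, l2: float = 0.01,
                 learning_rate: float = 0.008, decay_rate: float = 0.96,
                 decay_steps: int = 17, batch_size: int = 32,
                 max_epochs: int = 120, patience: int = 10,
                 validation_fraction: float = 0.2, random_state: int = None):
        self.mask_snp = mask_snp
        self.mask_expr = mask_expr
        self.subnetwork_activation = subnetwork_activation
        self.hidden1_size = hidden1_size
        self.hidden2_size = hidden2_size
        self.dropout_rate = dropout_rate
        self.l2 = l2
        self.learning_rate = learning_rate
        self.decay_rate = decay_rate
        self.decay_steps = decay_steps
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    @classmethod
    def from_config(cls, mask_snp: MaskStack, mask_expr: MaskStack, cfg: ModelConfig,
                    validation_fraction: float = 0.2) -> "ConstrainedPathwayClassifier":
        if mask_snp.depth != cfg.depth or mask_expr.depth != cfg.depth:
            raise ValueError(
                f"mask depths ({mask_snp.depth}, {mask_expr.depth}) do not match config depth {cfg.depth}"
            )
        return cls(
            mask_snp=mask_snp, mask_expr=mask_expr,
            subnetwork_activation=cfg.subnetwork_activation,
            hidden1_size=cfg.hidden1_size, hidden2_size=cfg.hidden2_size,
            dropout_rate=cfg.dropout_rate, l2=cfg.l2,
            learning_rate=cfg.learning_rate, decay_rate=cfg.decay_rate,
            decay_steps=cfg.decay_steps, batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs, patience=cfg.patience,
            validation_fraction=validation_fraction, random_state=cfg.seed,
        )

    def _subnet(self, stack: MaskStack) -> list:
        act = "linear" if self.subnetwork_activation == "identity" else self.subnetwork_activation
        return [
            Dense(m.shape[0], m.shape[1], act, frozen_mask=m)
            for m in stack.masks
        ]

    def _build_net(self, n_features: int, rng: np.random.Generator) -> MultimodalNet:
        if self.mask_snp is None or self.mask_expr is None:
            raise ValueError("mask_snp and mask_expr are required")
        if self.mask_snp.depth != self.mask_expr.depth:
            raise ValueError("the two mask stacks must share the same depth")
        slices = self._slices(n_features)
        top = (
            len(self.mask_snp.level_orders[-1])
            + len(self.mask_expr.level_orders[-1])
            + (slices["clinical"].stop - slices["clinical"].start)
        )
        return MultimodalNet(
            subnets=[self._subnet(self.mask_snp), self._subnet(self.mask_expr)],
            head=self._head(top, rng),
            slices=slices,
        )

    def subnetwork_weights(self) -> list[list[np.ndarray]]:
        check_is_fitted(self, "net_")
        return [[layer.W for layer in stack] for stack in self.net_.subnets]


class DenseBaselineClassifier(_BaseTriClassifier):
    """Unconstrained baseline: identical layer shapes, all weights trainable.

    The subnetwork dense layers keep the constrained widths (genes ->
    level-1 -> ... -> top) and, like the frozen versions, carry no biases;
    everything else matches :class:`ConstrainedPathwayClassifier`.
    """

    def __init__(self, mask_snp: MaskStack = None, mask_expr: MaskStack = None,
                 subnetwork_activation: str = "identity",
                 hidden1_size: int = 19, hidden2_size: int = 8,
                 dropout_rate: float = 0.597, l2: float = 0.01,
                 learning_rate: float = 0.008, decay_rate: float = 0.96,
                 decay_steps: int = 17, batch_size: int = 32,
                 max_epochs: int = 120, patience: int = 10,
                 validation_fraction: float = 0.2, random_state: int = None):
        self.mask_snp = mask_snp
        self.mask_expr = mask_expr
        self.subnetwork_activation = subnetwork_activation
        self.hidden1_size = hidden1_size
        self.hidden2_size = hidden2_size
        self.dropout_rate = dropout_rate
        self.l2 = l2
        self.learning_rate = learning_rate
        self.decay_rate = decay_rate
        self.decay_steps = decay_steps
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _subnet(self, stack: MaskStack, rng: np.random.Generator) -> list:
        act = "linear" if self.subnetwork_activation == "identity" else self.subnetwork_activation
        return [
            Dense(m.shape[0], m.shape[1], act, use_bias=False, rng=rng)
            for m in stack.masks
        ]

    def _build_net(self, n_features: int, rng: np.random.Generator) -> MultimodalNet:
        slices = self._slices(n_features)
        top = (
            len(self.mask_snp.level_orders[-1])
            + len(self.mask_expr.level_orders[-1])
            + (slices["clinical"].stop - slices["clinical"].start)
        )
        return MultimodalNet(
            subnets=[self._subnet(self.mask_snp, rng), self._subnet(self.mask_expr, rng)],
            head=self._head(top, rng),
            slices=slices,
        )


def count_parameters(model: _BaseTriClassifier) -> dict:
    """Walk the layers and count trainable / non-trainable parameters.

    Non-trainable: frozen mask nonzeros (the subnetwork weights) plus the
    batch-norm moving mean/variance.  Trainable: batch-norm scale/shift and
    the head (or, for the baseline, also subnetwork) dense weights and
    biases.  ``layer_count`` follows the 3-input + 2x``depth`` masked +
    concat + batch-norm + dense + dropout + dense + dense convention.
    """
    check_is_fitted(model, "net_")
    trainable = 0
    non_trainable = 0
    for layer in model.net_.all_layers():
        if isinstance(layer, Dense):
            size = layer.W.size if not layer.frozen else int(layer.W.sum())
            if layer.frozen:
                non_trainable += size
            else:
                trainable += layer.W.size + (0 if layer.b is None else layer.b.size)
        elif isinstance(layer, BatchNorm):
            trainable += layer.gamma.size + layer.beta.size
            non_trainable += layer.moving_mean.size + layer.moving_var.size
    per_subnet = [
        sum(int(l.W.sum()) if l.frozen else l.W.size for l in stack)
        for stack in model.net_.subnets
    ]
    depth = len(model.net_.subnets[0])
    return {
        "trainable": trainable,
        "non_trainable": non_trainable,
        "total": trainable + non_trainable,
        "layer_count": 3 + 2 * depth + 6,
        "subnetwork_parameters": per_subnet,
        "subnetwork_parameters_combined": int(sum(per_subnet)),
    }
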