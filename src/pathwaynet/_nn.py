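"""Minimal feed-forward machinery for the constrained classifier.

Only what the architecture needs: dense layers (optionally frozen to a
binary connectivity mask), batch normalisation, inverted dropout, Adam
with a staircase exponential learning-rate schedule, and a softmax
cross-entropy training loop with early stopping on validation loss.
Everything is plain numpy and deterministic given a seed.
"""

from __future__ import annotations

import copy

import numpy as np

_EPS_BN = 1e-3  # batch-norm variance epsilon
_ADAM_EPS = 1e-7


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear" or kind == "identity":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear" or kind == "identity":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "tanh":
        return 1.0 - a**2
    raise ValueError(f"unknown activation {kind!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Dense:
    """Fully connected layer.

    With ``frozen_mask`` set, the weight matrix *is* the 0/1 mask, there is
    no bias, and the layer contributes no trainable parameters — gradients
    stop accumulating here by construction.
    """

    def __init__(self, n_in: int, n_units: int, activation: str = "linear",
                 l2: float = 0.0, use_bias: bool = True,
                 frozen_mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None):
        self.activation = activation
        self.l2 = l2
        self.frozen = frozen_mask is not None
        if self.frozen:
            assert frozen_mask.shape == (n_in, n_units)
            self.W = frozen_mask.astype(float)
            self.b = None
        else:
            rng = rng or np.random.default_rng()
            limit = np.sqrt(6.0 / (n_in + n_units))  # Glorot uniform
            self.W = rng.uniform(-limit, limit, size=(n_in, n_units))
            self.b = np.zeros(n_units) if use_bias else None
        self.dW = np.zeros_like(self.W)
        self.db = None if self.b is None else np.zeros_like(self.b)

    def params(self):
        if self.frozen:
            return []
        out = [("W", self)]
        if self.b is not None:
            out.append(("b", self))
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.W
        if self.b is not None:
            z = z + self.b
        self._z = z
        self._a = _activate(z, self.activation)
        return self._a

    def backward(self, da: np.ndarray) -> np.ndarray:
        dz = da * _activate_grad(self._z, self._a, self.activation)
        if not self.frozen:
            self.dW = self._x.T @ dz + 2.0 * self.l2 * self.W
            if self.b is not None:
                self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def penalty(self) -> float:
        return 0.0 if self.frozen else float(self.l2 * np.sum(self.W**2))


class BatchNorm:
    """Batch normalisation; scale/shift trainable, moving statistics not."""

    def __init__(self, n_features: int, momentum: float = 0.99):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.moving_mean = np.zeros(n_features)
        self.moving_var = np.ones(n_features)
        self.momentum = momentum
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.frozen = False

    def params(self):
        return [("gamma", self), ("beta", self)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.moving_mean = self.momentum * self.moving_mean + (1 - self.momentum) * mean
            self.moving_var = self.momentum * self.moving_var + (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        self._x = x
        self._mean, self._var = mean, var
        self._std = np.sqrt(var + _EPS_BN)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, da: np.ndarray) -> np.ndarray:
        n = da.shape[0]
        self.dgamma = (da * self._xhat).sum(axis=0)
        self.dbeta = da.sum(axis=0)
        dxhat = da * self.gamma
        # full batch-statistics backward
        dvar = (dxhat * (self._x - self._mean) * -0.5 * self._std**-3).sum(axis=0)
        dmean = (-dxhat / self._std).sum(axis=0) + dvar * (-2.0 / n) * (self._x - self._mean).sum(axis=0)
        return dxhat / self._std + dvar * 2.0 * (self._x - self._mean) / n + dmean / n

    def penalty(self) -> float:
        return 0.0


class Dropout:
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.frozen = False
        self.rng = np.random.default_rng()

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, da: np.ndarray) -> np.ndarray:
        return da if self._mask is None else da * self._mask

    def penalty(self) -> float:
        return 0.0


class MultimodalNet:
    """Two gene->pathway subnetworks plus a clinical passthrough, fused by a
    batch-norm + dense head ending in 3 softmax logits.

    ``subnets`` is a list of two layer stacks applied to the SNP and
    expression slices of the input; the clinical slice bypasses them.  The
    head sees the concatenation ``[subnet1_top | subnet2_top | clinical]``.
    """

    def __init__(self, subnets: list[list], head: list, slices: dict[str, slice]):
        self.subnets = subnets
        self.head = head
        self.slices = slices

    # -- plumbing -----------------------------------------------------------
    def all_layers(self):
        for stack in self.subnets:
            yield from stack
        yield from self.head

    def trainable_arrays(self):
        """List of (layer, attr_name) for every trainable array."""
        out = []
        for layer in self.all_layers():
            for name, owner in layer.params():
                attr = {"W": "W", "b": "b", "gamma": "gamma", "beta": "beta"}[name]
                out.append((owner, attr))
        return out

    def get_state(self):
        return copy.deepcopy(
            [getattr(owner, attr) for owner, attr in self.trainable_arrays()]
            + [
                (l.moving_mean.copy(), l.moving_var.copy())
                for l in self.all_layers()
                if isinstance(l, BatchNorm)
            ]
        )

    def set_state(self, state):
        arrays = self.trainable_arrays()
        for (owner, attr), value in zip(arrays, state[: len(arrays)]):
            setattr(owner, attr, value.copy())
        bns = [l for l in self.all_layers() if isinstance(l, BatchNorm)]
        for layer, (mm, mv) in zip(bns, state[len(arrays):]):
            layer.moving_mean = mm.copy()
            layer.moving_var = mv.copy()

    # -- passes -------------------------------------------------------------
    def subnet_forward(self, X: np.ndarray, which: int, training: bool = False,
                       upto_level: int | None = None) -> np.ndarray:
        key = ["snp", "expression"][which]
        h = X[:, self.slices[key]]
        stack = self.subnets[which]
        n = len(stack) if upto_level is None else upto_level
        for layer in stack[:n]:
            h = layer.forward(h, training=training)
        return h

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        s1 = self.subnet_forward(X, 0, training=training)
        s2 = self.subnet_forward(X, 1, training=training)
        clin = X[:, self.slices["clinical"]]
        z = np.concatenate([s1, s2, clin], axis=1)
        self._widths = (s1.shape[1], s2.shape[1], clin.shape[1])
        for layer in self.head:
            z = layer.forward(z, training=training)
        return z  # logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward(X, training=False))

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.head):
            g = layer.backward(g)
        w1, w2, _ = self._widths
        g1, g2 = g[:, :w1], g[:, w1 : w1 + w2]
        for stack, gs in zip(self.subnets, (g1, g2)):
            if any(not layer.frozen for layer in stack):
                gg = gs
                for layer in reversed(stack):
                    gg = layer.backward(gg)

    def penalty(self) -> float:
        return float(sum(layer.penalty() for layer in self.all_layers()))


class Adam:
    """Adam with a staircase exponential learning-rate schedule:
    ``lr(t) = lr0 * decay_rate ** floor(t / decay_steps)`` at update step t."""

    def __init__(self, arrays, lr0: float = 0.008, decay_rate: float = 0.96,
                 decay_steps: int = 17, beta1: float = 0.9, beta2: float = 0.999):
        self.arrays = arrays  # list of (owner, attr)
        self.lr0, self.decay_rate, self.decay_steps = lr0, decay_rate, decay_steps
        self.beta1, self.beta2 = beta1, beta2
        self.t = 0
        self.m = [np.zeros_like(getattr(o, a)) for o, a in arrays]
        self.v = [np.zeros_like(getattr(o, a)) for o, a in arrays]
        self.lr_history: list[float] = []

    def lr_at(self, step: int) -> float:
        return self.lr0 * self.decay_rate ** (step // self.decay_steps)

    def step(self) -> None:
        lr = self.lr_at(self.t)
        self.lr_history.append(lr)
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        grad_attr = {"W": "dW", "b": "db", "gamma": "dgamma", "beta": "dbeta"}
        for i, (owner, attr) in enumerate(self.arrays):
            g = getattr(owner, grad_attr[attr])
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            update = lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + _ADAM_EPS)
            setattr(owner, attr, getattr(owner, attr) - update)


def cross_entropy(proba: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(proba, 1e-12, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def train_network(
    net: MultimodalNet,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray | None,
    Y_val: np.ndarray | None,
    *,
    batch_size: int = 32,
    max_epochs: int = 120,
    patience: int = 10,
    lr0: float = 0.008,
    decay_rate: float = 0.96,
    decay_steps: int = 17,
    rng: np.random.Generator | None = None,
) -> dict:
    """Softmax cross-entropy training with Adam and early stopping.

    Stops when validation loss fails to improve for ``patience`` epochs and
    restores the best weights.  Returns a history dict (per-epoch losses,
    accuracies, learning rate, plus the full per-step lr trace).
    """
    rng = rng or np.random.default_rng()
    for layer in net.all_layers():
        if isinstance(layer, Dropout):
            layer.rng = rng
    opt = Adam(net.trainable_arrays(), lr0=lr0, decay_rate=decay_rate, decay_steps=decay_steps)
    n = len(X_train)
    has_val = X_val is not None and len(X_val) > 0
    best_loss, best_state, best_epoch, wait = np.inf, None, -1, 0
    hist: dict = {"epoch": [], "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [], "lr": []}

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X_train[idx], Y_train[idx]
            logits = net.forward(xb, training=True)
            proba = softmax(logits)
            if not np.isfinite(proba).all():
                raise RuntimeError(f"NaN/Inf in network output at epoch {epoch}")
            net.backward((proba - yb) / len(xb))
            opt.step()

        tr_proba = net.predict_proba(X_train)
        tr_loss = cross_entropy(tr_proba, Y_train) + net.penalty()
        if not np.isfinite(tr_loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        tr_acc = float((tr_proba.argmax(1) == Y_train.argmax(1)).mean())
        hist["epoch"].append(epoch)
        hist["loss"].append(tr_loss)
        hist["accuracy"].append(tr_acc)
        hist["lr"].append(opt.lr_at(opt.t))
        if has_val:
            va_proba = net.predict_proba(X_val)
            va_loss = cross_entropy(va_proba, Y_val) + net.penalty()
            va_acc = float((va_proba.argmax(1) == Y_val.argmax(1)).mean())
            hist["val_loss"].append(va_loss)
            hist["val_accuracy"].append(va_acc)
            if va_loss < best_loss - 1e-12:
                best_loss, best_state, best_epoch, wait = va_loss, net.get_state(), epoch, 0
            else:
                wait += 1
                if wait >= patience:
                    break
        else:
            hist["val_loss"].append(np.nan)
            hist["val_accuracy"].append(np.nan)

    if has_val and best_state is not None:
        net.set_state(best_state)
    hist["best_epoch"] = best_epoch if has_val else hist["epoch"][-1] if hist["epoch"] else -1
    hist["stopped_epoch"] = hist["epoch"][-1] if hist["epoch"] else -1
    hist["lr_steps"] = list(opt.lr_history)
    return hist
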