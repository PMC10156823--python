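"""Neural-network building blocks on top of :mod:`unitednet.autodiff`.

Each layer supports three views of the same parameters:

* ``__call__(x, train)`` — autodiff forward used during training;
* ``np_forward(x)`` — plain-numpy inference forward (deterministic);
* ``multipliers(m_out, x_in, x_ref)`` — DeepLIFT-style multiplier
  backpropagation used by the layer-wise Shapley estimator.  Linear and
  inference-mode batch-norm layers propagate multipliers exactly;
  elementwise nonlinearities use the rescale rule
  ``(f(x) - f(x̄)) / (x - x̄)`` with a local-gradient fallback when the
  input equals its reference.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

_RESCALE_EPS = 1e-9


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        raise NotImplementedError

    def np_forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def multipliers(
        self, m_out: np.ndarray, x_in: np.ndarray, x_ref: np.ndarray
    ) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer ``y = x W + b`` with Kaiming-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def parameters(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x @ self.W + self.b

    def np_forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    def multipliers(self, m_out, x_in, x_ref):
        return m_out @ self.W.data.T


class ReLU(Layer):
    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.relu()

    def np_forward(self, x):
        return np.maximum(x, 0.0)

    def multipliers(self, m_out, x_in, x_ref):
        delta_in = x_in - x_ref
        delta_out = self.np_forward(x_in) - self.np_forward(x_ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = delta_out / delta_in
        grad = (x_in > 0).astype(float)
        scale = np.where(np.abs(delta_in) < _RESCALE_EPS, grad, scale)
        return m_out * scale


class Sigmoid(Layer):
    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.sigmoid()

    def np_forward(self, x):
        return 1.0 / (1.0 + np.exp(-x))

    def multipliers(self, m_out, x_in, x_ref):
        delta_in = x_in - x_ref
        delta_out = self.np_forward(x_in) - self.np_forward(x_ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = delta_out / delta_in
        s = self.np_forward(x_in)
        scale = np.where(np.abs(delta_in) < _RESCALE_EPS, s * (1 - s), scale)
        return m_out * scale


class BatchNorm(Layer):
    """1-D batch normalization.

    Training mode normalizes by batch statistics (differentiated through);
    inference mode is a fixed affine map using running averages, which is
    what the Shapley estimator sees.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if train and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            )
            return self.gamma * (centered / (var + self.eps).sqrt()) + self.beta
        scale = self.gamma * (1.0 / np.sqrt(self.running_var + self.eps))
        return scale * (x - self.running_mean) + self.beta

    def np_forward(self, x):
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        return scale * (x - self.running_mean) + self.beta.data

    def multipliers(self, m_out, x_in, x_ref):
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        return m_out * scale


class Scale(Layer):
    """Fixed elementwise/scalar multiplication ``y = c · x`` (no params)."""

    def __init__(self, c: float | np.ndarray):
        self.c = c

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x * self.c

    def np_forward(self, x):
        return x * self.c

    def multipliers(self, m_out, x_in, x_ref):
        return m_out * self.c


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer(x, train=train)
        return x

    def np_forward(self, x):
        for layer in self.layers:
            x = layer.np_forward(x)
        return x


def mlp(
    n_in: int,
    hidden: list[int],
    n_out: int,
    rng: np.random.Generator,
    *,
    batch_norm: bool = True,
    out_sigmoid: bool = False,
) -> Sequential:
    """Standard MLP: Dense → (BatchNorm) → ReLU blocks, linear output."""
    layers: list[Layer] = []
    prev = n_in
    for width in hidden:
        layers.append(Dense(prev, width, rng))
        if batch_norm:
            layers.append(BatchNorm(width))
        layers.append(ReLU())
        prev = width
    layers.append(Dense(prev, n_out, rng))
    if out_sigmoid:
        layers.append(Sigmoid())
    return Sequential(*layers)


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 10.0,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
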