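"""Low-level NumPy neural-network primitives.

Hand-derived forward/backward passes for the small, fixed set of layers the
model uses: batch normalization over arbitrary axes, strided max pooling,
clipped exponential activation, ReLU, dropout, and an Adam optimizer.

Everything operates on float64 arrays; training is deterministic given the
RNG that produced the minibatch order and dropout masks.
"""

from __future__ import annotations

import numpy as np

BN_EPS = 1e-5
BN_MOMENTUM = 0.1
EXP_CLIP = 20.0  # pre-activation ceiling before exponentiation


# --------------------------------------------------------------------------
# batch normalization
# --------------------------------------------------------------------------

class BatchNormState:
    """Learnable scale/shift plus running statistics for one BN layer.

    ``axes`` are the reduction axes (the remaining axes index features).
    """

    def __init__(self, shape, axes):
        self.gamma = np.ones(shape)
        self.beta = np.zeros(shape)
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)
        self.axes = tuple(axes)

    def copy(self) -> "BatchNormState":
        out = BatchNormState(self.gamma.shape, self.axes)
        out.gamma = self.gamma.copy()
        out.beta = self.beta.copy()
        out.running_mean = self.running_mean.copy()
        out.running_var = self.running_var.copy()
        return out


def bn_forward(x, state: BatchNormState, training: bool):
    """Batch-normalize ``x`` over ``state.axes``; returns (y, cache)."""
    if training:
        mean = x.mean(axis=state.axes)
        var = x.var(axis=state.axes)
        n = x.size // mean.size
        # running stats use the unbiased variance estimate
        unbiased = var * (n / max(n - 1, 1))
        state.running_mean += BN_MOMENTUM * (mean - state.running_mean)
        state.running_var += BN_MOMENTUM * (unbiased - state.running_var)
    else:
        mean, var = state.running_mean, state.running_var
    mean_b = np.expand_dims(mean, state.axes) if mean.ndim else mean
    var_b = np.expand_dims(var, state.axes) if var.ndim else var
    inv_std = 1.0 / np.sqrt(var_b + BN_EPS)
    xhat = (x - mean_b) * inv_std
    gamma_b = np.expand_dims(state.gamma, state.axes) if state.gamma.ndim else state.gamma
    beta_b = np.expand_dims(state.beta, state.axes) if state.beta.ndim else state.beta
    y = gamma_b * xhat + beta_b
    cache = (xhat, inv_std, gamma_b, state.axes, training)
    return y, cache


def bn_backward(dy, cache):
    """Gradient of bn_forward; returns (dx, dgamma, dbeta)."""
    xhat, inv_std, gamma_b, axes, training = cache
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    if not training:
        return dy * gamma_b * inv_std, dgamma, dbeta
    n = dy.size // dgamma.size
    dxhat = dy * gamma_b
    mean_dxhat = np.expand_dims(dxhat.mean(axis=axes), axes)
    mean_dxhat_xhat = np.expand_dims((dxhat * xhat).mean(axis=axes), axes)
    dx = inv_std * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
    return dx, dgamma, dbeta


# --------------------------------------------------------------------------
# activations
# --------------------------------------------------------------------------

def exp_forward(x):
    """exp with the pre-activation clipped at EXP_CLIP for stability."""
    clipped = np.minimum(x, EXP_CLIP)
    y = np.exp(clipped)
    return y, (y, x < EXP_CLIP)


def exp_backward(dy, cache):
    y, open_mask = cache
    return dy * y * open_mask


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, (x > 0.0)


def relu_backward(dy, mask):
    return dy * mask


def dropout_forward(x, rate, rng, training):
    """Inverted dropout; identity in evaluation mode or when rate == 0."""
    if not training or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


# --------------------------------------------------------------------------
# pooling
# --------------------------------------------------------------------------

def maxpool_forward(x, kernel, stride):
    """Max pool along axis 1 of an (N, P, U) array.

    Returns (pooled (N, Pp, U), argpos (N, Pp, U) absolute positions in P).
    Ties resolve to the lowest position (np.argmax convention).
    """
    n, p, u = x.shape
    pp = (p - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=1)[:, ::stride]
    # windows: (N, Pp, U, kernel)
    arg = windows.argmax(axis=-1)
    pooled = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
    starts = (np.arange(pp) * stride)[None, :, None]
    return pooled, arg + starts


def maxpool_backward(dy, argpos, input_shape):
    """Scatter pooled gradients back to their argmax positions."""
    dx = np.zeros(input_shape)
    n, pp, u = dy.shape
    n_idx = np.repeat(np.arange(n), pp * u)
    u_idx = np.tile(np.arange(u), n * pp)
    np.add.at(dx, (n_idx, argpos.ravel(), u_idx), dy.ravel())
    return dx


def global_maxpool_forward(x):
    """Max over axis 1 of (N, P, U); returns (pooled (N, U), argpos)."""
    arg = x.argmax(axis=1)
    pooled = np.take_along_axis(x, arg[:, None, :], axis=1)[:, 0, :]
    return pooled, arg


def global_maxpool_backward(dy, argpos, input_shape):
    dx = np.zeros(input_shape)
    n, p, u = input_shape
    n_idx = np.repeat(np.arange(n), u)
    u_idx = np.tile(np.arange(u), n)
    np.add.at(dx, (n_idx, argpos.ravel(), u_idx), dy.ravel())
    return dx


# --------------------------------------------------------------------------
# initialization and optimization
# --------------------------------------------------------------------------

def uniform_fan_in(rng, shape, fan_in):
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place)."""

    def __init__(self, lr=0.003, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if g is None:
                continue
            p = params[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
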