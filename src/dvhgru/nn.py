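"""Minimal GRU sequence regressor in NumPy: forward, BPTT, Adam.

Implements the standard gated recurrent unit

.. math::

    r_t &= \\sigma(W_{ir} x_t + b_{ir} + W_{hr} h_{t-1} + b_{hr}) \\\\
    z_t &= \\sigma(W_{iz} x_t + b_{iz} + W_{hz} h_{t-1} + b_{hz}) \\\\
    n_t &= \\tanh(W_{in} x_t + b_{in} + r_t \\odot (W_{hn} h_{t-1} + b_{hn})) \\\\
    h_t &= (1 - z_t) \\odot n_t + z_t \\odot h_{t-1}

with stacked layers, a per-step affine output head, and inverted dropout on
the top hidden state during training.  Gate weights for one layer are packed
as ``W_ih`` of shape (3H, I) and ``W_hh`` of shape (3H, H) in the row order
(reset, update, candidate), with separate input- and hidden-side biases.

Everything is float64 and fully deterministic given the seeds handed in; the
backward pass is verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["GRUParams", "init_params", "forward", "backward", "Adam"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUParams:
    """Flat container of all trainable arrays.

    ``layers[l] = (W_ih, W_hh, b_ih, b_hh)``; ``w_out`` (H,), ``b_out`` scalar.
    """

    layers: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    w_out: np.ndarray
    b_out: np.ndarray  # shape ()

    @property
    def hidden_size(self) -> int:
        return self.layers[0][1].shape[1]

    @property
    def input_size(self) -> int:
        return self.layers[0][0].shape[1]

    def flatten(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W_ih, W_hh, b_ih, b_hh in self.layers:
            out += [W_ih, W_hh, b_ih, b_hh]
        out += [self.w_out, self.b_out]
        return out

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.flatten()))

    def copy(self) -> "GRUParams":
        return GRUParams(
            layers=[tuple(a.copy() for a in layer) for layer in self.layers],
            w_out=self.w_out.copy(),
            b_out=self.b_out.copy(),
        )


def init_params(
    input_size: int, hidden_size: int, num_layers: int, seed: int
) -> GRUParams:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization, deterministic in seed."""
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(hidden_size)
    layers = []
    for l in range(num_layers):
        in_size = input_size if l == 0 else hidden_size
        W_ih = rng.uniform(-bound, bound, size=(3 * hidden_size, in_size))
        W_hh = rng.uniform(-bound, bound, size=(3 * hidden_size, hidden_size))
        b_ih = rng.uniform(-bound, bound, size=3 * hidden_size)
        b_hh = rng.uniform(-bound, bound, size=3 * hidden_size)
        layers.append((W_ih, W_hh, b_ih, b_hh))
    w_out = rng.uniform(-bound, bound, size=hidden_size)
    b_out = np.zeros(())
    return GRUParams(layers=layers, w_out=w_out, b_out=b_out)


def forward(
    params: GRUParams,
    x: np.ndarray,
    dropout_p: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the network over a batch of sequences.

    Parameters
    ----------
    x : (B, T, I) array
        Batch of input sequences.
    dropout_p : float
        Inverted-dropout probability applied to the top hidden states before
        the output head; active only when a generator is supplied (training).

    Returns
    -------
    y : (B, T) per-step scalar outputs.
    cache : intermediates needed by :func:`backward`.
    """
    B, T, _ = x.shape
    H = params.hidden_size
    layer_caches = []
    inp = x
    for W_ih, W_hh, b_ih, b_hh in params.layers:
        h = np.zeros((B, H))
        steps = []
        hs = np.empty((B, T, H))
        for t in range(T):
            xt = inp[:, t, :]
            gi = xt @ W_ih.T + b_ih
            gh = h @ W_hh.T + b_hh
            r = _sigmoid(gi[:, :H] + gh[:, :H])
            z = _sigmoid(gi[:, H : 2 * H] + gh[:, H : 2 * H])
            a_nh = gh[:, 2 * H :]
            n = np.tanh(gi[:, 2 * H :] + r * a_nh)
            h_new = (1.0 - z) * n + z * h
            steps.append((h, r, z, n, a_nh))
            h = h_new
            hs[:, t, :] = h
        layer_caches.append({"input": inp, "steps": steps})
        inp = hs
    top = inp  # (B, T, H)
    if dropout_p > 0.0 and dropout_rng is not None:
        mask = (dropout_rng.random(top.shape) >= dropout_p) / (1.0 - dropout_p)
    else:
        mask = None
    dropped = top * mask if mask is not None else top
    y = dropped @ params.w_out + float(params.b_out)
    cache = {"layer_caches": layer_caches, "dropped": dropped, "mask": mask}
    return y, cache


def backward(params: GRUParams, cache: dict, dy: np.ndarray) -> GRUParams:
    """Gradients of a scalar loss wrt all parameters, given dL/dy (B, T)."""
    B, T = dy.shape
    H = params.hidden_size
    dropped = cache["dropped"]
    mask = cache["mask"]
    d_w_out = np.einsum("bt,bth->h", dy, dropped)
    d_b_out = np.asarray(dy.sum())
    d_top = dy[:, :, None] * params.w_out  # (B, T, H)
    if mask is not None:
        d_top = d_top * mask

    grad_layers: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    d_out = d_top  # gradient wrt this layer's output sequence
    for l in range(len(params.layers) - 1, -1, -1):
        W_ih, W_hh, b_ih, b_hh = params.layers[l]
        lc = cache["layer_caches"][l]
        inp = lc["input"]
        steps = lc["steps"]
        dW_ih = np.zeros_like(W_ih)
        dW_hh = np.zeros_like(W_hh)
        db_ih = np.zeros_like(b_ih)
        db_hh = np.zeros_like(b_hh)
        d_inp = np.empty_like(inp)
        dh = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, r, z, n, a_nh = steps[t]
            dh = dh + d_out[:, t, :]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            da_n = dn * (1.0 - n * n)
            dr = da_n * a_nh
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            da_nh = da_n * r
            gi_grad = np.concatenate([da_r, da_z, da_n], axis=1)  # (B, 3H)
            gh_grad = np.concatenate([da_r, da_z, da_nh], axis=1)
            xt = inp[:, t, :]
            dW_ih += gi_grad.T @ xt
            dW_hh += gh_grad.T @ h_prev
            db_ih += gi_grad.sum(axis=0)
            db_hh += gh_grad.sum(axis=0)
            d_inp[:, t, :] = gi_grad @ W_ih
            dh = dh * z + gh_grad @ W_hh
        grad_layers.append((dW_ih, dW_hh, db_ih, db_hh))
        d_out = d_inp
    grad_layers.reverse()
    return GRUParams(layers=grad_layers, w_out=d_w_out, b_out=d_b_out)


class Adam:
    """Adam optimizer over a :class:`GRUParams` container."""

    def __init__(
        self,
        params: GRUParams,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(a) for a in params.flatten()]
        self.v = [np.zeros_like(a) for a in params.flatten()]

    def step(self, params: GRUParams, grads: GRUParams) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(zip(params.flatten(), grads.flatten())):
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
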