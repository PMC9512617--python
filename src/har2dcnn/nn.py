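"""Framework-free convolutional network primitives.

All operations are plain NumPy on float64 arrays, written so that the
analytic backward pass can be checked against central finite differences to
high precision.  Conventions:

* A feature-map block has shape ``(C, H, W)`` or batched ``(N, C, H, W)``.
* A kernel set has weights of shape ``(C_in, C_out, K_h, K_w)`` — indexed by
  (input map, output map, row, col) — and a bias per output map.
* Convolution is "valid" (no padding) with strides ``(h_s, w_s)``; the output
  height is ``floor((H − K_h)/h_s) + 1`` and analogously for width.
* The forward pre-activation is
  ``z[o, i, j] = Σ_c Σ_{u,v} a[c, o, u, v] · x[c, i·h_s + u, j·w_s + v] + b[o]``.
* The activation σ is ReLU with σ′(0) := 0.
* Backpropagation sends a layer's residual δ = ∂L/∂z to the previous layer by
  correlating with the 180°-rotated kernels over the full boundary, then
  multiplying elementwise by σ′(z_prev); the weight gradient is the
  input-patch/δ contraction.  Both are exercised against finite differences
  in the test-suite.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import GeometryError, ParameterError

__all__ = [
    "conv2d_forward",
    "conv1d_forward",
    "conv_output_shape",
    "relu",
    "relu_grad",
    "maxpool_forward",
    "maxpool_backward",
    "conv_backward_input",
    "conv_backward_delta",
    "conv_weight_grad",
    "softmax",
    "dense_softmax_forward",
    "cross_entropy",
    "finite_difference_grads",
]


def _as_batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        return x[None], False
    if x.ndim == 4:
        return x, True
    raise GeometryError(f"expected (C, H, W) or (N, C, H, W); got shape {x.shape}")


def conv_output_shape(in_dim: int, kernel: int, stride: int) -> int:
    if kernel > in_dim:
        raise GeometryError(f"kernel extent {kernel} exceeds input extent {in_dim}")
    if stride < 1:
        raise GeometryError("stride must be >= 1")
    return (in_dim - kernel) // stride + 1


def conv2d_forward(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    strides: tuple[int, int] = (1, 1),
) -> np.ndarray:
    """Valid strided 2-D convolution (cross-correlation) over all input maps."""
    xb, batched = _as_batched(x)
    weights = np.asarray(weights, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if weights.ndim != 4:
        raise GeometryError("weights must be (C_in, C_out, K_h, K_w)")
    c_in, c_out, kh, kw = weights.shape
    if xb.shape[1] != c_in:
        raise GeometryError(
            f"input has {xb.shape[1]} maps but kernel expects {c_in}"
        )
    if bias.shape != (c_out,):
        raise GeometryError(f"bias must have shape ({c_out},); got {bias.shape}")
    hs, ws = strides
    conv_output_shape(xb.shape[2], kh, hs)
    conv_output_shape(xb.shape[3], kw, ws)
    win = sliding_window_view(xb, (kh, kw), axis=(2, 3))[:, :, ::hs, ::ws]
    out = np.einsum("ncijuv,couv->noij", win, weights, optimize=True)
    out += bias[:, None, None]
    return out if batched else out[0]


def conv1d_forward(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    strides: tuple[int, int] = (1, 1),
) -> np.ndarray:
    """Time-axis-only convolution: a 2-D convolution whose kernels have height
    1, so each row (channel) of the picture is filtered independently."""
    if np.asarray(weights).shape[2] != 1:
        raise GeometryError("conv1d requires kernel height K_h = 1")
    return conv2d_forward(x, weights, bias, strides)


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def relu_grad(z: np.ndarray) -> np.ndarray:
    """σ′ for ReLU; the kink at 0 takes derivative 0."""
    return (np.asarray(z) > 0).astype(np.float64)


def maxpool_forward(
    x: np.ndarray, pool: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint-tile max pooling.

    Pool dims must divide the map dims (pad-free tiling).  Returns the pooled
    maps and the flat within-tile argmax record (first index wins on ties)
    used to route gradients in :func:`maxpool_backward`.
    """
    xb, batched = _as_batched(x)
    ph, pw = pool
    n, c, h, w = xb.shape
    if ph < 1 or pw < 1:
        raise GeometryError("pool dims must be >= 1")
    if h % ph or w % pw:
        raise GeometryError(f"pool dims {pool} do not tile map dims {(h, w)}")
    tiles = xb.reshape(n, c, h // ph, ph, w // pw, pw)
    tiles = tiles.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // ph, w // pw, ph * pw)
    arg = tiles.argmax(axis=-1)
    out = np.take_along_axis(tiles, arg[..., None], axis=-1)[..., 0]
    if not batched:
        out, arg = out[0], arg[0]
    return out, arg


def maxpool_backward(
    dout: np.ndarray, argmax: np.ndarray, pool: tuple[int, int], input_shape
) -> np.ndarray:
    """Scatter pooled-output gradients back to the recorded max positions."""
    db, batched = _as_batched(dout) if np.asarray(dout).ndim in (3, 4) else (None, None)
    if db is None:
        raise GeometryError("dout must be (C, Ho, Wo) or (N, C, Ho, Wo)")
    arg = argmax if batched else argmax[None]
    ph, pw = pool
    n, c, ho, wo = db.shape
    tiles = np.zeros((n, c, ho, wo, ph * pw))
    np.put_along_axis(tiles, arg[..., None], db[..., None], axis=-1)
    dx = (
        tiles.reshape(n, c, ho, wo, ph, pw)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho * ph, wo * pw)
    )
    full = np.zeros((n, *input_shape[-3:]))
    full[:, :, : ho * ph, : wo * pw] = dx
    return full if batched else full[0]


def conv_backward_input(
    delta: np.ndarray,
    weights: np.ndarray,
    strides: tuple[int, int],
    input_shape,
) -> np.ndarray:
    """∂L/∂x for a conv layer given that layer's residual δ = ∂L/∂z.

    For stride 1 this is the full correlation of δ with the 180°-rotated
    kernels; for larger strides the same scatter pattern applies to the
    strided positions only.
    """
    db, batched = _as_batched(delta)
    weights = np.asarray(weights, dtype=np.float64)
    c_in, c_out, kh, kw = weights.shape
    hs, ws = strides
    n, _, ho, wo = db.shape
    hin, win_ = input_shape[-2], input_shape[-1]
    dx = np.zeros((n, c_in, hin, win_))
    for u in range(kh):
        for v in range(kw):
            contrib = np.einsum("noij,co->ncij", db, weights[:, :, u, v])
            dx[:, :, u : u + hs * (ho - 1) + 1 : hs, v : v + ws * (wo - 1) + 1 : ws] += contrib
    return dx if batched else dx[0]


def conv_backward_delta(
    delta: np.ndarray,
    weights: np.ndarray,
    strides: tuple[int, int],
    z_prev: np.ndarray,
) -> np.ndarray:
    """Residual of the previous layer:
    ``δ_prev = (Σ_o δ_o ⊛ rot180(a)) ⊙ σ′(z_prev)``."""
    dx = conv_backward_input(delta, weights, strides, np.asarray(z_prev).shape)
    return dx * relu_grad(z_prev)


def conv_weight_grad(
    delta: np.ndarray,
    x_prev: np.ndarray,
    kernel: tuple[int, int],
    strides: tuple[int, int] = (1, 1),
) -> tuple[np.ndarray, np.ndarray]:
    """Weight and bias gradients of a conv layer.

    ``dW[c, o, u, v] = Σ_{(n),i,j} x[c, i·h_s + u, j·w_s + v] · δ[o, i, j]``
    and ``db[o] = Σ δ[o, i, j]``, summed over the batch when present.
    """
    xb, _ = _as_batched(x_prev)
    db_, _ = _as_batched(delta)
    kh, kw = kernel
    hs, ws = strides
    win = sliding_window_view(xb, (kh, kw), axis=(2, 3))[:, :, ::hs, ::ws]
    ho, wo = db_.shape[2], db_.shape[3]
    if win.shape[2] != ho or win.shape[3] != wo:
        raise GeometryError(
            f"delta shape {db_.shape} inconsistent with input {xb.shape}, "
            f"kernel {kernel}, strides {strides}"
        )
    dw = np.einsum("ncijuv,noij->couv", win, db_, optimize=True)
    dbias = db_.sum(axis=(0, 2, 3))
    return dw, dbias


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax over the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dense_softmax_forward(
    features: np.ndarray, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Fully connected layer followed by softmax: class probabilities that are
    strictly positive and sum to 1."""
    f = np.asarray(features, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    b = np.asarray(bias, dtype=np.float64)
    if w.ndim != 2 or w.shape[1] != f.shape[-1]:
        raise GeometryError(
            f"weights must be (C, {f.shape[-1]}); got {w.shape}"
        )
    return softmax(f @ w.T + b)


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-300) -> float:
    """Mean categorical cross-entropy of integer targets ``y``."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 1:
        p = p[None]
        y = np.atleast_1d(y)
    picked = p[np.arange(len(y)), np.asarray(y, dtype=int)]
    return float(-np.mean(np.log(np.maximum(picked, eps))))


def finite_difference_grads(
    loss_fn: Callable[[], float],
    params: Mapping[str, np.ndarray],
    epsilon: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Central finite differences of ``loss_fn`` w.r.t. every entry of every
    parameter array, perturbing in place: ``(L(θ+ε) − L(θ−ε)) / (2ε)``.

    This is the independent oracle against which the analytic backward pass
    is validated; it shares no code with it.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    grads: dict[str, np.ndarray] = {}
    for name, arr in params.items():
        g = np.zeros_like(arr, dtype=np.float64)
        flat = arr.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + epsilon
            lp = loss_fn()
            flat[i] = orig - epsilon
            lm = loss_fn()
            flat[i] = orig
            gflat[i] = (lp - lm) / (2.0 * epsilon)
        grads[name] = g
    return grads
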