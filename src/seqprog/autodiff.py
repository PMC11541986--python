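"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains feed-forward and convolutional risk models with
gradient descent; this module provides the small tape-based autodiff
engine those models run on.  Only the operations the models need are
implemented: elementwise arithmetic with broadcasting, matmul, the
usual nonlinearities, reductions, concatenation/slicing, and 3D
(strided / transposed) convolution.

Most functions here dispatch on their input: given plain ndarrays they
return ndarrays, given :class:`Tensor` they build the tape.  Loss
functions elsewhere in the package are therefore written once and work
both as pure numpy references and as differentiable training losses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "exp", "log", "sigmoid", "tanh", "softplus",
    "relu", "prelu", "matmul", "concatenate", "tsum", "tmean", "where_const",
    "conv3d", "conv_transpose3d", "Adam", "numeric_gradient",
]


def _acc(t: "Tensor", g: np.ndarray) -> None:
    """Accumulate a gradient contribution (lazy allocation)."""
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor dispatch to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators -----------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = astensor(other)
        out_data = fwd(self.data, other.data)
        parents = (self, other)

        def backward(g):
            if self.requires_grad:
                _acc(self, _unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                _acc(other, _unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor(out_data, parents=parents, backward=backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return astensor(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b, lambda g, a, b: -g * a / b ** 2)

    def __rtruediv__(self, other):
        return astensor(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, k):
        k = float(k)

        def backward(g):
            if self.requires_grad:
                _acc(self, g * k * self.data ** (k - 1))

        return Tensor(self.data ** k, parents=(self,), backward=backward)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, idx, g)

        return Tensor(self.data[idx], parents=(self,), backward=backward)

    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape

        def backward(g):
            if self.requires_grad:
                _acc(self, g.reshape(self.data.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=backward)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def detach(self):
        return Tensor(self.data.copy())


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# -- elementwise functions (dispatch on ndarray vs Tensor) -------------------

def _unary(x, fwd, dfwd):
    if not isinstance(x, Tensor):
        return fwd(np.asarray(x, dtype=np.float64))
    out_data = fwd(x.data)

    def backward(g):
        if x.requires_grad:
            _acc(x, g * dfwd(x.data, out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def exp(x):
    return _unary(x, np.exp, lambda a, o: o)


def log(x):
    return _unary(x, np.log, lambda a, o: 1.0 / a)


def _sigmoid(a):
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def sigmoid(x):
    return _unary(x, _sigmoid, lambda a, o: o * (1.0 - o))


def tanh(x):
    return _unary(x, np.tanh, lambda a, o: 1.0 - o ** 2)


def softplus(x):
    fwd = lambda a: np.logaddexp(0.0, a)
    return _unary(x, fwd, lambda a, o: _sigmoid(a))


def relu(x):
    return _unary(x, lambda a: np.maximum(a, 0.0), lambda a, o: (a > 0).astype(float))


def prelu(x, alpha):
    """PReLU with learnable slope `alpha` for negative inputs (fused op)."""
    if not (isinstance(x, Tensor) or isinstance(alpha, Tensor)):
        return np.where(np.asarray(x) > 0, x, alpha * np.asarray(x))
    xt, at = astensor(x), astensor(alpha)
    neg = xt.data <= 0
    out = np.where(neg, at.data * xt.data, xt.data)

    def backward(g):
        if xt.requires_grad:
            _acc(xt, np.where(neg, g * at.data, g))
        if at.requires_grad:
            _acc(at, _unbroadcast(np.where(neg, g * xt.data, 0.0), at.data.shape))

    return Tensor(out, parents=(xt, at), backward=backward)


def where_const(cond, x, y):
    """Select between two differentiable branches with a constant mask."""
    cond = np.asarray(cond)
    if not _is_t(x, y):
        return np.where(cond, x, y)
    x, y = astensor(x), astensor(y)

    def backward(g):
        if x.requires_grad:
            _acc(x, _unbroadcast(np.where(cond, g, 0.0), x.data.shape))
        if y.requires_grad:
            _acc(y, _unbroadcast(np.where(cond, 0.0, g), y.data.shape))

    return Tensor(np.where(cond, x.data, y.data), parents=(x, y), backward=backward)


def matmul(a, b):
    if not _is_t(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = astensor(a), astensor(b)

    def backward(g):
        if a.requires_grad:
            ga = g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data)
            _acc(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = a.data.T @ g if a.data.ndim == 2 else np.outer(a.data, g)
            _acc(b, _unbroadcast(gb, b.data.shape))

    return Tensor(a.data @ b.data, parents=(a, b), backward=backward)


def tsum(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        if axis is None:
            _acc(x, np.broadcast_to(g, x.data.shape))
        else:
            gk = g if keepdims else np.expand_dims(g, axis)
            _acc(x, np.broadcast_to(gk, x.data.shape))

    return Tensor(np.sum(x.data, axis=axis, keepdims=keepdims),
                  parents=(x,), backward=backward)


def tmean(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.mean(x, axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(x, axis=axis, keepdims=keepdims) / float(n)


def concatenate(parts, axis=0):
    if not _is_t(*parts):
        return np.concatenate(parts, axis=axis)
    parts = [astensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _acc(p, g[tuple(sl)])

    return Tensor(np.concatenate([p.data for p in parts], axis=axis),
                  parents=tuple(parts), backward=backward)


# -- 3D convolution ----------------------------------------------------------

def _pad5(x, pad):
    if pad == 0:
        return x
    shape = x.shape[:2] + tuple(s + 2 * pad for s in x.shape[2:])
    out = np.zeros(shape, dtype=x.dtype)
    out[:, :, pad:-pad, pad:-pad, pad:-pad] = x
    return out


def conv3d(x, w, b=None, stride: int = 1, pad: int = 0):
    """3D cross-correlation.  x: (N,C,D,H,W), w: (O,C,kd,kh,kw), b: (O,).

    Implemented as k^3 shifted-slice matmuls (fast and memory-light
    compared with materializing the full sliding-window tensor).
    """
    xt, wt = astensor(x), astensor(w)
    bt = astensor(b) if b is not None else None
    s, k = stride, wt.data.shape[2]
    xp = _pad5(xt.data, pad)
    N, C = xp.shape[:2]
    Do = (xp.shape[2] - k) // s + 1
    Ho = (xp.shape[3] - k) // s + 1
    Wo = (xp.shape[4] - k) // s + 1
    O = wt.data.shape[0]

    def _slice(i, j, l):
        return xp[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s]

    out_l = np.zeros((N, Do, Ho, Wo, O), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                # (N,C,Do,Ho,Wo) x (O,C) -> (N,Do,Ho,Wo,O)
                out_l += np.tensordot(_slice(i, j, l), wt.data[:, :, i, j, l],
                                      axes=([1], [1]))
    out = np.moveaxis(out_l, -1, 1)
    if bt is not None:
        out = out + bt.data[None, :, None, None, None]

    def backward(g):
        if bt is not None and bt.requires_grad:
            _acc(bt, g.sum(axis=(0, 2, 3, 4)))
        need_x = xt.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(wt.data) if wt.requires_grad else None
        gl = np.moveaxis(g, 1, -1)          # (N,Do,Ho,Wo,O), contiguous once
        gl = np.ascontiguousarray(gl)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    if gw is not None:
                        gw[:, :, i, j, l] = np.tensordot(
                            gl, _slice(i, j, l),
                            axes=([0, 1, 2, 3], [0, 2, 3, 4]))
                    if need_x:
                        t = np.tensordot(gl, wt.data[:, :, i, j, l],
                                         axes=([4], [0]))   # (N,Do,Ho,Wo,C)
                        gxp[:, :, i:i + s * Do:s, j:j + s * Ho:s,
                            l:l + s * Wo:s] += np.moveaxis(t, -1, 1)
        if gw is not None:
            _acc(wt, gw)
        if need_x:
            _acc(xt, gxp[:, :, pad:-pad, pad:-pad, pad:-pad] if pad else gxp)

    parents = (xt, wt) if bt is None else (xt, wt, bt)
    return Tensor(out, parents=parents, backward=backward)


def conv_transpose3d(x, w, b=None, stride: int = 2):
    """Transposed 3D convolution, kernel == stride (non-overlapping upsampling).

    x: (N,C,D,H,W), w: (C,O,k,k,k) with k == stride; output (N,O,D*k,H*k,W*k).
    """
    xt, wt = astensor(x), astensor(w)
    bt = astensor(b) if b is not None else None
    k = wt.data.shape[2]
    if k != stride:
        raise ValueError("conv_transpose3d requires kernel == stride")
    N, C, D, H, W = xt.data.shape
    O = wt.data.shape[1]
    out = np.einsum("ncdhw,coijk->nodihjwk", xt.data, wt.data, optimize=True)
    out = out.reshape(N, O, D * k, H * k, W * k)
    if bt is not None:
        out = out + bt.data[None, :, None, None, None]

    def backward(g):
        g6 = g.reshape(N, O, D, k, H, k, W, k)
        if wt.requires_grad:
            _acc(wt, np.einsum("nodihjwk,ncdhw->coijk", g6, xt.data, optimize=True))
        if bt is not None and bt.requires_grad:
            _acc(bt, g.sum(axis=(0, 2, 3, 4)))
        if xt.requires_grad:
            _acc(xt, np.einsum("nodihjwk,coijk->ncdhw", g6, wt.data, optimize=True))

    parents = (xt, wt) if bt is None else (xt, wt, bt)
    return Tensor(out, parents=parents, backward=backward)


# -- optimization ------------------------------------------------------------

class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (testing aid)."""
    g = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
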