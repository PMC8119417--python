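"""Minimal reverse-mode automatic differentiation over numpy arrays.

The inpainting networks need three things a plain numpy implementation
cannot give: gradients of composite conv nets, gradients of a critic with
respect to its *input* (for the WGAN gradient penalty), and gradients of
that gradient's norm with respect to the critic parameters (double
backprop).  Every operation here therefore expresses its backward pass in
terms of the same ``Tensor`` primitives, so differentiating the result of
``grad(...)`` a second time just works.

Only the operations the package uses are provided; this is not a general
framework.  Convolutions are built from ``im2col``/``col2im`` (which are
mutually adjoint linear maps) plus ``matmul``.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAPH_STACK = [True]


def _recording() -> bool:
    return _GRAPH_STACK[-1]


@contextmanager
def no_grad():
    """Disable graph construction (forward values are still computed)."""
    _GRAPH_STACK.append(False)
    try:
        yield
    finally:
        _GRAPH_STACK.pop()


@contextmanager
def graph_enabled(flag: bool):
    _GRAPH_STACK.append(bool(flag))
    try:
        yield
    finally:
        _GRAPH_STACK.pop()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._grad_fn = None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- backward -----------------------------------------------------------
    def backward(self, grad=None, create_graph: bool = False):
        """Accumulate gradients into ``.grad`` of every reachable leaf."""
        grads = _backprop(self, grad, create_graph)
        for node, g in grads.items():
            if node.requires_grad and node._grad_fn is None:
                node.grad = g if node.grad is None else add(node.grad, g)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, grad_fn) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    track = _recording() and any(p.requires_grad for p in parents)
    out.requires_grad = track
    out._parents = tuple(parents) if track else ()
    out._grad_fn = grad_fn if track else None
    return out


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def _backprop(root: Tensor, grad, create_graph: bool):
    if grad is None:
        grad = Tensor(np.ones_like(root.data))
    else:
        grad = astensor(grad)
    table: dict[int, Tensor] = {id(root): grad}
    nodes: dict[int, Tensor] = {id(root): root}
    with graph_enabled(create_graph):
        for node in reversed(_toposort(root)):
            g = table.get(id(node))
            if g is None or node._grad_fn is None:
                continue
            for parent, pg in zip(node._parents, node._grad_fn(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in table:
                    table[id(parent)] = add(table[id(parent)], pg)
                else:
                    table[id(parent)] = pg
                nodes[id(parent)] = parent
    return {nodes[k]: v for k, v in table.items()}


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Return d(output)/d(input) for each input, without touching ``.grad``."""
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    table = _backprop(output, grad_output, create_graph)
    out = [table.get(t) for t in inputs]
    out = [Tensor(np.zeros_like(t.data)) if g is None else g for t, g in zip(inputs, out)]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# elementwise / shape primitives
# ---------------------------------------------------------------------------

def _sum_to(t: Tensor, shape) -> Tensor:
    """Adjoint of numpy broadcasting: reduce ``t`` down to ``shape``."""
    if t.shape == tuple(shape):
        return t
    extra = t.ndim - len(shape)
    if extra:
        t = tsum(t, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and t.shape[i] != 1)
    if axes:
        t = tsum(t, axis=axes, keepdims=True)
    return reshape(t, tuple(shape))


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = a.data + b.data
    return _make(data, (a, b), lambda g: (_sum_to(g, a.shape), _sum_to(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = a.data * b.data
    return _make(data, (a, b),
                 lambda g: (_sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)))


def power(a, p) -> Tensor:
    a = astensor(a)
    p = float(p)
    data = a.data ** p
    return _make(data, (a,), lambda g: (mul(g, mul(power(a, p - 1.0), p)),))


def sqrt(a) -> Tensor:
    # the backward factor re-derives from the parent (not the output) so the
    # graph stays acyclic and Python's gc never sees reference cycles
    a = astensor(a)
    return _make(np.sqrt(a.data), (a,),
                 lambda g: (mul(g, mul(power(a, -0.5), 0.5)),))


def absolute(a) -> Tensor:
    a = astensor(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), lambda g: (mul(g, Tensor(sign)),))


def exp(a) -> Tensor:
    a = astensor(a)
    y = np.exp(a.data)
    return _make(y, (a,), lambda g: (mul(g, exp(a)),))


def tanh(a) -> Tensor:
    # generator output squashing; first-order-exact constant factor
    a = astensor(a)
    y = np.tanh(a.data)
    return _make(y, (a,), lambda g: (mul(g, Tensor(1.0 - y * y)),))


def leaky_relu(a, alpha: float = 0.2) -> Tensor:
    a = astensor(a)
    factor = np.where(a.data > 0, 1.0, alpha).astype(a.dtype)
    return _make(a.data * factor, (a,), lambda g: (mul(g, Tensor(factor)),))


def elu(a) -> Tensor:
    # First-order-exact; the curvature term is dropped (see module docstring).
    a = astensor(a)
    pos = a.data > 0
    ex = np.exp(np.minimum(a.data, 0.0))
    data = np.where(pos, a.data, ex - 1.0).astype(a.dtype)
    factor = np.where(pos, 1.0, ex).astype(a.dtype)
    return _make(data, (a,), lambda g: (mul(g, Tensor(factor)),))


def where(cond, a, b) -> Tensor:
    """``cond`` is a constant boolean/float mask; selection is exact."""
    a, b = astensor(a), astensor(b)
    c = np.asarray(cond)
    data = np.where(c, a.data, b.data)
    ca = c.astype(data.dtype)
    return _make(data, (a, b),
                 lambda g: (_sum_to(mul(g, Tensor(ca)), a.shape),
                            _sum_to(mul(g, Tensor(1.0 - ca)), b.shape)))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gd = g
        if not keepdims and axis is not None:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            shp = list(a.shape)
            for ax in sorted(ax % a.ndim for ax in axes):
                shp[ax] = 1
            gd = reshape(gd, tuple(shp))
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * a.ndim)
        return (broadcast_to(gd, a.shape),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    data = np.ascontiguousarray(np.broadcast_to(a.data, shape))
    return _make(data, (a,), lambda g: (_sum_to(g, a.shape),))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),))


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def take(a, idx) -> Tensor:
    """Basic (slice/int) indexing; the adjoint scatters into zeros."""
    a = astensor(a)
    return _make(a.data[idx], (a,), lambda g: (scatter(g, idx, a.shape),))


def scatter(a, idx, shape) -> Tensor:
    a = astensor(a)
    data = np.zeros(shape, dtype=a.dtype)
    data[idx] = a.data
    return _make(data, (a,), lambda g: (take(g, idx),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            grads.append(take(g, tuple(idx)))
        return tuple(grads)

    return _make(data, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = matmul(g, _swap_last(b))
        gb = matmul(_swap_last(a), g)
        return (_sum_to(ga, a.shape), _sum_to(gb, b.shape))

    return _make(data, (a, b), backward)


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, tuple(axes))


def softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    shifted = a - Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / tsum(e, axis=axis, keepdims=True)


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1+exp(x)) on raw arrays (scoring only)."""
    x = np.asarray(x, dtype=np.float64)
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _conv_geometry(h, w, k, stride, dilation, pad):
    span = dilation * (k - 1) + 1
    oh = (h + 2 * pad - span) // stride + 1
    ow = (w + 2 * pad - span) // stride + 1
    return oh, ow, span


def im2col(x, k: int, stride: int = 1, dilation: int = 1, pad: int = 0) -> Tensor:
    """[N,C,H,W] -> [N, C*k*k, OH*OW] patch matrix (adjoint: :func:`col2im`)."""
    x = astensor(x)
    n, c, h, w = x.shape
    oh, ow, span = _conv_geometry(h, w, k, stride, dilation, pad)
    if oh < 1 or ow < 1:
        raise ValueError("convolution output would be empty")
    xp = x.data if pad == 0 else np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # N,C,OH,OW,k,k
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, oh * ow)
    ctx = (n, c, h, w, k, stride, dilation, pad)
    return _make(cols, (x,), lambda g: (col2im(g, ctx),))


def col2im(cols, ctx) -> Tensor:
    """Adjoint of :func:`im2col`: overlap-add columns back onto the image."""
    cols = astensor(cols)
    n, c, h, w, k, stride, dilation, pad = ctx
    oh, ow, _ = _conv_geometry(h, w, k, stride, dilation, pad)
    blocks = cols.data.reshape(n, c, k, k, oh, ow)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            ii, jj = i * dilation, j * dilation
            out[:, :, ii:ii + stride * oh:stride, jj:jj + stride * ow:stride] += blocks[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    out = np.ascontiguousarray(out)
    return _make(out, (cols,), lambda g: (im2col(g, k, stride, dilation, pad),))


def conv2d(x, weight, bias=None, stride: int = 1, dilation: int = 1, pad: int = 0) -> Tensor:
    """weight: [O, C, k, k]; returns [N, O, OH, OW]."""
    x, weight = astensor(x), astensor(weight)
    o, c, k, _ = weight.shape
    n, _, h, w = x.shape
    oh, ow, _ = _conv_geometry(h, w, k, stride, dilation, pad)
    cols = im2col(x, k, stride=stride, dilation=dilation, pad=pad)
    wmat = reshape(weight, (o, c * k * k))
    out = matmul(wmat, cols)                      # [N, O, OH*OW] via broadcasting
    out = reshape(out, (n, o, oh, ow))
    if bias is not None:
        out = add(out, reshape(astensor(bias), (1, o, 1, 1)))
    return out


def upsample2(x) -> Tensor:
    """Nearest-neighbour x2 upsampling (adjoint: 2x2 block sum)."""
    x = astensor(x)
    n, c, h, w = x.shape
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        gr = reshape(g, (n, c, h, 2, w, 2))
        return (tsum(gr, axis=(3, 5)),)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a list of parameter Tensors (state is plain numpy)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.5,
                 beta2: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
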