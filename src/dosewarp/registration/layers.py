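"""Minimal 3D neural-network layers with explicit backward passes.

Everything operates on single samples (channel-first arrays, no batch axis) in
float64 numpy.  Convolutions are implemented as im2col + GEMM; the transposed
convolution is the exact adjoint of the strided convolution with the same
geometry, so ``out = (in - 1) * stride + kernel - 2 * pad`` per axis.
Gradients accumulate into ``Param.grad`` and are applied by ``Adam``.
Finite-difference tests in the suite verify every layer's backward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3, got {v!r}")
    return t  # type: ignore[return-value]


class Param:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k, s, p):
    """x: (cin, X, Y, Z) -> (cols (N, cin*k^3), out_spatial)."""
    xp = np.pad(x, ((0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    win = sliding_window_view(xp, k, axis=(1, 2, 3))
    win = win[:, :: s[0], :: s[1], :: s[2]]
    cin = x.shape[0]
    ox, oy, oz = win.shape[1:4]
    cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        ox * oy * oz, cin * k[0] * k[1] * k[2]
    )
    return cols, (ox, oy, oz)


def _col2im(cols: np.ndarray, cin: int, spatial, k, s, p, lattice):
    """Adjoint of _im2col: scatter columns back onto a (cin, *spatial) array."""
    ox, oy, oz = lattice
    g = cols.reshape(ox, oy, oz, cin, k[0], k[1], k[2])
    gpad = np.zeros(
        (cin, spatial[0] + 2 * p[0], spatial[1] + 2 * p[1], spatial[2] + 2 * p[2])
    )
    for dx in range(k[0]):
        for dy in range(k[1]):
            for dz in range(k[2]):
                gpad[
                    :,
                    dx : dx + s[0] * ox : s[0],
                    dy : dy + s[1] * oy : s[1],
                    dz : dz + s[2] * oz : s[2],
                ] += g[..., dx, dy, dz].transpose(3, 0, 1, 2)
    return gpad[
        :,
        p[0] : p[0] + spatial[0],
        p[1] : p[1] + spatial[1],
        p[2] : p[2] + spatial[2],
    ]


class Conv3d:
    def __init__(
        self,
        cin,
        cout,
        kernel=3,
        stride=1,
        pad=1,
        rng=None,
        zero_init=False,
        input_grad=True,
    ):
        self.cin, self.cout = cin, cout
        self.k = _triple(kernel)
        self.s = _triple(stride)
        self.p = _triple(pad)
        self.input_grad = input_grad  # False for layers fed by raw images
        fan_in = cin * self.k[0] * self.k[1] * self.k[2]
        if zero_init:
            w = np.zeros((cout, fan_in))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def out_shape(self, spatial):
        return tuple(
            (spatial[a] + 2 * self.p[a] - self.k[a]) // self.s[a] + 1 for a in range(3)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        spatial = x.shape[1:]
        for a in range(3):
            if spatial[a] + 2 * self.p[a] < self.k[a]:
                raise ValueError(
                    f"axis {a}: size {spatial[a]} too small for kernel {self.k[a]}"
                )
        cols, lattice = _im2col(x, self.k, self.s, self.p)
        y = cols @ self.weight.value.T + self.bias.value
        self._cache = (cols, spatial, lattice)
        return np.ascontiguousarray(
            y.reshape(*lattice, self.cout).transpose(3, 0, 1, 2)
        )

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, spatial, lattice = self._cache
        gflat = g.transpose(1, 2, 3, 0).reshape(-1, self.cout)
        self.weight.grad += gflat.T @ cols
        self.bias.grad += gflat.sum(axis=0)
        if not self.input_grad:
            return None
        gcols = gflat @ self.weight.value
        return _col2im(gcols, self.cin, spatial, self.k, self.s, self.p, lattice)


class ConvTranspose3d:
    """Adjoint of a strided convolution; used for progressive upsampling."""

    def __init__(self, cin, cout, kernel, stride, pad=1, rng=None, zero_init=False):
        self.cin, self.cout = cin, cout
        self.k = _triple(kernel)
        self.s = _triple(stride)
        self.p = _triple(pad)
        fan_in = cin * self.k[0] * self.k[1] * self.k[2]
        if zero_init:
            w = np.zeros((cin, cout * self.k[0] * self.k[1] * self.k[2]))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(
                0.0,
                np.sqrt(2.0 / fan_in),
                size=(cin, cout * self.k[0] * self.k[1] * self.k[2]),
            )
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def out_shape(self, spatial):
        return tuple(
            (spatial[a] - 1) * self.s[a] + self.k[a] - 2 * self.p[a] for a in range(3)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        lattice = x.shape[1:]
        target = self.out_shape(lattice)
        xflat = x.reshape(self.cin, -1).T  # (N_in, cin)
        cols = xflat @ self.weight.value  # (N_in, cout*k^3)
        y = _col2im(cols, self.cout, target, self.k, self.s, self.p, lattice)
        y += self.bias.value[:, None, None, None]
        self._cache = (xflat, lattice, target)
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        xflat, lattice, target = self._cache
        self.bias.grad += g.sum(axis=(1, 2, 3))
        gcols, got_lattice = _im2col(g, self.k, self.s, self.p)
        assert got_lattice == lattice
        self.weight.grad += xflat.T @ gcols
        gx = gcols @ self.weight.value.T  # (N_in, cin)
        return np.ascontiguousarray(gx.T.reshape(self.cin, *lattice))


class Linear:
    def __init__(self, din, dout, rng=None, zero_init=False):
        self.din, self.dout = din, dout
        if zero_init:
            w = np.zeros((dout, din))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / din), size=(dout, din))
        self.weight = Param(w)
        self.bias = Param(np.zeros(dout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += g.T @ x
        self.bias.grad += g.sum(axis=0)
        return g @ self.weight.value


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)


class Adam:
    """Standard Adam with bias correction (lr 1e-4 default per the training recipe)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
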