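"""Unsupervised registration losses.

Two terms drive training:

* ``lncc`` — squared local normalized cross-correlation between the fixed
  image and the warped moving image, computed over cubic windows of edge
  ``n`` (default 9) voxels.  The per-window correlation is squared, so the
  similarity is invariant to a global sign flip of either image and lies in
  [0, 1]; the training loss is its negation.
* ``diffusion_regularizer`` — squared spatial gradient of the displacement
  field, penalizing non-smooth fields.

Both expose analytic gradients (``*_with_grad``) used by the hand-written
backward pass of the networks; finite-difference tests in the suite verify
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from ..grids import DisplacementField, Volume3D
from .warp import warp_with_grad

EPS_DEFAULT = 1e-5


@dataclass
class LossWeights:
    """Weighting of the smoothness term (λ in the total loss)."""

    lambda_smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")


def _window_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Sum of x over the n^3 window centred at each voxel (zero padded)."""
    return uniform_filter(x, size=n, mode="constant", cval=0.0) * float(n**3)


def _lncc_terms(f: np.ndarray, g: np.ndarray, n: int, eps: float):
    v = float(n**3)
    sf = _window_sum(f, n)
    sg = _window_sum(g, n)
    sff = _window_sum(f * f, n)
    sgg = _window_sum(g * g, n)
    sfg = _window_sum(f * g, n)
    a = sfg - sf * sg / v
    b = sff - sf * sf / v
    c = sgg - sg * sg / v
    d = b * c + eps
    cc = a * a / d
    return sf, sg, a, b, c, d, cc


def _check_window(shape, n: int) -> None:
    if n < 1 or n % 2 == 0:
        raise ValueError(f"LNCC window must be a positive odd integer, got {n}")
    if any(n > s for s in shape):
        raise ValueError(f"LNCC window {n} exceeds volume shape {shape}")


def lncc(fixed: np.ndarray, warped: np.ndarray, n: int = 9, eps: float = EPS_DEFAULT) -> float:
    """Mean squared local correlation; 1 means locally identical structure."""
    fixed = np.asarray(fixed, dtype=np.float64)
    warped = np.asarray(warped, dtype=np.float64)
    if fixed.shape != warped.shape:
        raise ValueError("fixed and warped must share a grid")
    _check_window(fixed.shape, n)
    *_, cc = _lncc_terms(fixed, warped, n, eps)
    return float(cc.mean())


def lncc_loss(fixed: np.ndarray, warped: np.ndarray, n: int = 9, eps: float = EPS_DEFAULT) -> float:
    """Negated similarity: the quantity training minimizes."""
    return -lncc(fixed, warped, n, eps)


def lncc_loss_with_grad(
    fixed: np.ndarray, warped: np.ndarray, n: int = 9, eps: float = EPS_DEFAULT
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the warped image."""
    f = np.asarray(fixed, dtype=np.float64)
    g = np.asarray(warped, dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError("fixed and warped must share a grid")
    _check_window(f.shape, n)
    v = float(n**3)
    sf, sg, a, b, c, d, cc = _lncc_terms(f, g, n, eps)
    fbar = sf / v
    gbar = sg / v
    alpha = 2.0 * a / d
    beta = 2.0 * a * a * b / (d * d)
    # d cc_p / d g_q = alpha_p (f_q - fbar_p) - beta_p (g_q - gbar_p); sum over
    # the windows containing q via box filters (the window is symmetric).
    grad = (
        f * _window_sum(alpha, n)
        - _window_sum(alpha * fbar, n)
        - g * _window_sum(beta, n)
        + _window_sum(beta * gbar, n)
    )
    nvox = f.size
    return -float(cc.mean()), -grad / nvox


def _axis_gradient(u: np.ndarray, axis: int) -> np.ndarray:
    """Central differences with one-sided boundaries (np.gradient convention)."""
    return np.gradient(u, axis=axis)


def _axis_gradient_adjoint(v: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of ``_axis_gradient`` along ``axis`` (n >= 3)."""
    v = np.moveaxis(v, axis, 0)
    out = np.zeros_like(v)
    out[0] -= v[0]
    out[1] += v[0]
    out[:-2] -= v[1:-1] / 2.0
    out[2:] += v[1:-1] / 2.0
    out[-2] -= v[-1]
    out[-1] += v[-1]
    return np.moveaxis(out, 0, axis)


def diffusion_regularizer(field, reduce: str = "sum") -> float:
    """Squared spatial gradient of the displacement field.

    ``reduce="sum"`` gives the plain sum over voxels of ``||∇u(p)||²``
    (all 9 partial derivatives, in mm per voxel step); ``reduce="mean"``
    divides by ``3 * n_voxels`` so the value is grid-size independent
    (the normalization the training loss uses).  Zero iff the field is
    constant.
    """
    u = field.u if isinstance(field, DisplacementField) else np.asarray(field)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("expected a (nx,ny,nz,3) displacement array")
    total = 0.0
    for comp in range(3):
        for axis in range(3):
            g = _axis_gradient(u[..., comp], axis)
            total += float((g * g).sum())
    if reduce == "sum":
        return total
    if reduce == "mean":
        return total / (3.0 * u[..., 0].size)
    raise ValueError(f"unknown reduce {reduce!r}")


def diffusion_grad(u: np.ndarray, reduce: str = "mean") -> np.ndarray:
    """Gradient of ``diffusion_regularizer`` with respect to the field."""
    grad = np.zeros_like(u, dtype=np.float64)
    for comp in range(3):
        for axis in range(3):
            g = _axis_gradient(u[..., comp], axis)
            grad[..., comp] += _axis_gradient_adjoint(2.0 * g, axis)
    if reduce == "mean":
        grad /= 3.0 * u[..., 0].size
    elif reduce != "sum":
        raise ValueError(f"unknown reduce {reduce!r}")
    return grad


def total_loss(
    fixed: Volume3D | np.ndarray,
    moving: Volume3D | np.ndarray,
    field: DisplacementField | np.ndarray,
    weights: LossWeights | float = LossWeights(),
    n: int = 9,
    eps: float = EPS_DEFAULT,
) -> float:
    """Similarity loss of the warped pair plus λ times the smoothness term.

    The smoothness term uses the mean reduction so λ = 1 is a sensible
    default independent of grid size.
    """
    lam = weights.lambda_smooth if isinstance(weights, LossWeights) else float(weights)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    fdat = fixed.data if isinstance(fixed, Volume3D) else np.asarray(fixed)
    mdat = moving.data if isinstance(moving, Volume3D) else np.asarray(moving)
    if isinstance(field, DisplacementField):
        u, spacing = field.u, field.spacing
    else:
        u = np.asarray(field)
        spacing = fixed.spacing if isinstance(fixed, Volume3D) else (1.0, 1.0, 1.0)
    warped, _ = warp_with_grad(mdat, u, spacing)
    sim = lncc_loss(fdat, warped, n=n, eps=eps)
    smooth = diffusion_regularizer(u, reduce="mean")
    return sim + lam * smooth


def total_loss_with_grad(
    fixed: np.ndarray,
    moving: np.ndarray,
    u: np.ndarray,
    spacing,
    lam: float,
    n: int = 9,
    eps: float = EPS_DEFAULT,
) -> tuple[float, np.ndarray]:
    """Total loss and its gradient with respect to the displacement field."""
    warped, warp_back = warp_with_grad(moving, u, spacing)
    sim, g_warped = lncc_loss_with_grad(fixed, warped, n=n, eps=eps)
    g_u = warp_back(g_warped)
    smooth = diffusion_regularizer(u, reduce="mean")
    g_u += lam * diffusion_grad(u, reduce="mean")
    return sim + lam * smooth, g_u
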