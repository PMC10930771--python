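"""Differentiable image sampling: bilinear lookup and linearized multi-sampling.

Coordinates are normalised to [-1, 1] with the "align corners" convention
(-1 maps onto the first pixel centre, +1 onto the last), so sampling an
H x W image on the identity grid of the same size reproduces it exactly.
Lookups outside the raster return black (zero), matching the padding/filter
colour used throughout the pipeline.

The linearized sampler evaluates each grid point together with ``k_aux``
randomly jittered auxiliary points, fits a least-squares linear model
``value ~ a + b*x + c*y`` through them, and returns the fitted value at the
grid point.  Gradients with respect to the sample coordinates are taken
from the fitted slopes ``(b, c)`` rather than from the local bilinear
kernel, which keeps them informative under heavy minification.

The batched entry point :func:`affine_sample` processes slides in chunks
sized to bound transient memory (the auxiliary-point value tensor is the
largest intermediate).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, _node, astensor

__all__ = [
    "affine_sample",
    "base_grid",
    "bilinear_eval",
    "linearized_eval",
]

_CHUNK_ELEMS = 6_000_000  # max auxiliary sample points held at once


def base_grid(out_side: int) -> tuple[np.ndarray, np.ndarray]:
    """Return the identity meshgrid ``(gx, gy)`` spanning [-1, 1]^2."""
    coords = np.linspace(-1.0, 1.0, out_side)
    gx, gy = np.meshgrid(coords, coords)  # gx varies along columns (x axis)
    return gx, gy


def _bilinear_batch(rows: np.ndarray, x: np.ndarray, y: np.ndarray,
                    H: int, W: int, with_grads: bool = False):
    """Evaluate batched channels-last images (B, H*W, C) at points (B, M).

    Returns values (and optionally d/dx, d/dy) of shape (B, M, C).
    """
    dt = rows.dtype
    u = (x + 1.0) * np.asarray(0.5 * (W - 1), dtype=dt)
    v = (y + 1.0) * np.asarray(0.5 * (H - 1), dtype=dt)
    u0f = np.floor(u)
    v0f = np.floor(v)
    fu = (u - u0f)[..., None]
    fv = (v - v0f)[..., None]
    u0 = u0f.astype(np.int64)
    v0 = v0f.astype(np.int64)

    def corner(vi, ui):
        valid = ((ui >= 0) & (ui < W) & (vi >= 0) & (vi < H))[..., None]
        idx = (
            np.minimum(np.maximum(vi, 0), H - 1) * W
            + np.minimum(np.maximum(ui, 0), W - 1)
        )
        vals = np.stack([r[i] for r, i in zip(rows, idx)])  # (B, M, C)
        vals *= valid
        return vals

    p00 = corner(v0, u0)
    p01 = corner(v0, u0 + 1)
    p10 = corner(v0 + 1, u0)
    p11 = corner(v0 + 1, u0 + 1)
    top = p00 + (p01 - p00) * fu
    bot = p10 + (p11 - p10) * fu
    vals = top + (bot - top) * fv
    if not with_grads:
        return vals
    dv_du = (p01 - p00) * (1.0 - fv) + (p11 - p10) * fv
    dv_dv = bot - top
    return vals, dv_du * (0.5 * (W - 1)), dv_dv * (0.5 * (H - 1))


def _linearized_batch(rows, x, y, H, W, k_aux, noise_sd, rng):
    """Linearized multi-sampling for batched channels-last images; returns
    values and the fitted slopes used as coordinate gradients, (B, N, C)."""
    B, N = x.shape
    n_pts = k_aux + 1
    dt = x.dtype
    dx = np.zeros((B, n_pts, N), dtype=dt)
    dy = np.zeros((B, n_pts, N), dtype=dt)
    sd = np.asarray(noise_sd, dtype=dt)
    if dt == np.float32:
        dx[:, 1:] = rng.standard_normal((B, k_aux, N), dtype=np.float32) * sd
        dy[:, 1:] = rng.standard_normal((B, k_aux, N), dtype=np.float32) * sd
    else:
        dx[:, 1:] = rng.normal(0.0, noise_sd, size=(B, k_aux, N))
        dy[:, 1:] = rng.normal(0.0, noise_sd, size=(B, k_aux, N))
    pts_x = (x[:, None, :] + dx).reshape(B, n_pts * N)
    pts_y = (y[:, None, :] + dy).reshape(B, n_pts * N)
    C = rows.shape[-1]
    vals_all = _bilinear_batch(rows, pts_x, pts_y, H, W).reshape(B, n_pts, N, C)

    # normal-equation terms accumulated in float64 for stability
    Sx = dx.sum(axis=1, dtype=np.float64)
    Sy = dy.sum(axis=1, dtype=np.float64)
    Sxx = (dx * dx).sum(axis=1, dtype=np.float64)
    Syy = (dy * dy).sum(axis=1, dtype=np.float64)
    Sxy = (dx * dy).sum(axis=1, dtype=np.float64)
    T0 = vals_all.sum(axis=1, dtype=np.float64)  # (B, N, C)
    Tx = (vals_all * dx[..., None]).sum(axis=1, dtype=np.float64)
    Ty = (vals_all * dy[..., None]).sum(axis=1, dtype=np.float64)

    # cofactor inverse of the symmetric 3x3 normal matrix, vectorised
    a00 = Sxx * Syy - Sxy**2
    a01 = Sy * Sxy - Sx * Syy
    a02 = Sx * Sxy - Sy * Sxx
    a11 = n_pts * Syy - Sy**2
    a12 = Sx * Sy - n_pts * Sxy
    a22 = n_pts * Sxx - Sx**2
    det = n_pts * a00 + Sx * a01 + Sy * a02
    scale = n_pts * (Sxx + Syy + 1e-300) ** 2
    degenerate = np.abs(det) <= 1e-12 * scale
    det_safe = np.where(degenerate, 1.0, det)[..., None]

    a00, a01, a02 = a00[..., None], a01[..., None], a02[..., None]
    a11, a12, a22 = a11[..., None], a12[..., None], a22[..., None]
    vals = (a00 * T0 + a01 * Tx + a02 * Ty) / det_safe
    bx = (a01 * T0 + a11 * Tx + a12 * Ty) / det_safe
    by = (a02 * T0 + a12 * Tx + a22 * Ty) / det_safe

    if np.any(degenerate):
        cvals, cdx, cdy = _bilinear_batch(rows, x, y, H, W, with_grads=True)
        deg = degenerate[..., None]
        vals = np.where(deg, cvals, vals)
        bx = np.where(deg, cdx, bx)
        by = np.where(deg, cdy, by)
    return vals, bx, by


# -- single-image conveniences (numpy in / numpy out) ------------------------


def bilinear_eval(image: np.ndarray, x: np.ndarray, y: np.ndarray,
                  with_grads: bool = False):
    """Evaluate one image (C,H,W) at flat normalised points ``x``, ``y``."""
    C, H, W = image.shape
    rows = np.ascontiguousarray(image.reshape(C, H * W).T)[None]
    out = _bilinear_batch(rows, x[None], y[None], H, W, with_grads)
    if with_grads:
        return tuple(o[0].T for o in out)
    return out[0].T


def linearized_eval(image: np.ndarray, x: np.ndarray, y: np.ndarray,
                    k_aux: int, noise_sd: float, rng: np.random.Generator):
    """Linearized multi-sample of one image (C,H,W); returns (vals, bx, by).

    Degenerate fits (e.g. the zero-noise limit) fall back to plain bilinear
    interpolation with analytic derivatives.
    """
    if k_aux < 1:
        raise ValueError("k_aux must be >= 1")
    C, H, W = image.shape
    rows = np.ascontiguousarray(image.reshape(C, H * W).T)[None]
    vals, bx, by = _linearized_batch(
        rows, x[None], y[None], H, W, k_aux, noise_sd, rng
    )
    return vals[0].T, bx[0].T, by[0].T


# -- the autodiff operation --------------------------------------------------


def affine_sample(images: np.ndarray, s: Tensor, tx: Tensor, ty: Tensor,
                  out_side: int, k_aux: int = 8, noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Sample each image under its affine transform ``x -> s*x + t``.

    ``images`` is a constant (B, C, H, W) array; ``s``, ``tx``, ``ty`` are
    length-B tensors.  Gradients flow to the transform parameters only (the
    source pixels come straight from the pyramid reader and carry none).
    With ``noise_sd == 0`` the sampler reduces to bilinear interpolation
    with analytic coordinate gradients; otherwise linearized multi-sampling
    is used.
    """
    s, tx, ty = astensor(s), astensor(tx), astensor(ty)
    images = np.asarray(images)
    if images.dtype != np.float64:
        images = images.astype(np.float32)
    B, C, H, W = images.shape
    rows = np.ascontiguousarray(images.reshape(B, C, H * W).transpose(0, 2, 1))
    gx, gy = base_grid(out_side)
    gx = gx.ravel().astype(images.dtype)
    gy = gy.ravel().astype(images.dtype)
    N = gx.shape[0]
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng()
    x_all = s.data[:, None] * gx + tx.data[:, None]  # (B, N)
    y_all = s.data[:, None] * gy + ty.data[:, None]

    out = np.empty((B, C, N), dtype=images.dtype)
    bx_all = np.empty((B, C, N), dtype=images.dtype)
    by_all = np.empty((B, C, N), dtype=images.dtype)
    chunk = max(1, _CHUNK_ELEMS // (N * (k_aux + 1)))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        if noise_sd > 0:
            vals, bx, by = _linearized_batch(
                rows[lo:hi], x_all[lo:hi], y_all[lo:hi], H, W,
                k_aux, noise_sd, rng,
            )
        else:
            vals, bx, by = _bilinear_batch(
                rows[lo:hi], x_all[lo:hi], y_all[lo:hi], H, W, with_grads=True
            )
        out[lo:hi] = vals.transpose(0, 2, 1)
        bx_all[lo:hi] = bx.transpose(0, 2, 1)
        by_all[lo:hi] = by.transpose(0, 2, 1)

    def vjp_s(g):
        gf = g.reshape(B, C, N)
        dgx = (gf * bx_all).sum(axis=1)  # (B, N)
        dgy = (gf * by_all).sum(axis=1)
        return dgx @ gx + dgy @ gy

    def vjp_tx(g):
        return (g.reshape(B, C, N) * bx_all).sum(axis=(1, 2))

    def vjp_ty(g):
        return (g.reshape(B, C, N) * by_all).sum(axis=(1, 2))

    return _node(out.reshape(B, C, out_side, out_side),
                 (s, tx, ty), (vjp_s, vjp_tx, vjp_ty))
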