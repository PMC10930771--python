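"""The differentiable hard-attention core.

A "Branch" runs five parallel convolution stacks of increasing receptive
field (1x1; 1x1-3x3; 1x1-3x3-3x3; 1x1-3x3-3x3-3x3; maxpool-1x1), each path
preserving the spatial size, concatenates them along channels, and projects
to a single-channel map.  A spatial sparsemax turns that map into a sparse
probability mass function over the 56 x 56 view, from which the affine crop
parameters are inferred:

* ``tx``, ``ty`` — expected cell-centre coordinate along each axis;
* ``s`` — expected L1 deviation of the coordinates from that centroid, so a
  point mass yields the minimum zoom window while uniform attention yields
  ``s ~ 1`` (no zoom).

The constraints ``s = max(s, 0.05)``, ``t = tanh(t)`` then bound the
transform, and the grid generator maps the base meshgrid through
``x -> s*x + t``.  Sampling uses linearized multi-sampling (see
:mod:`magnet._sampling`) so that scale changes do not starve the transform
parameters of gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._sampling import base_grid, bilinear_eval, linearized_eval
from ._tensor import Tensor, astensor, concatenate
from ._tensor import maximum as t_maximum
from ._tensor import sparsemax as t_sparsemax
from ._tensor import sparsemax_array
from .errors import ContractError

__all__ = [
    "AffineParams",
    "Branch",
    "bilinear_sample",
    "constrain_params",
    "constrain_params_t",
    "infer_affine_params",
    "infer_affine_params_t",
    "linearized_sample",
    "localize",
    "make_grid",
    "sparsemax",
]

S_FLOOR = 0.05


@dataclass(frozen=True)
class AffineParams:
    """Constrained affine crop parameters and the 2 x 3 matrix they induce."""

    s: float
    tx: float
    ty: float

    @property
    def theta(self) -> np.ndarray:
        return np.array([[self.s, 0.0, self.tx], [0.0, self.s, self.ty]])

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(1.0, 0.0, 0.0)


def sparsemax(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Projection of ``values`` onto the probability simplex (numpy-in/out)."""
    return sparsemax_array(values, axis=axis)


def _conv_bn_relu(cin: int, cout: int, kernel: int, rng) -> nn.Sequential:
    # padding preserves spatial size: 1 for 3x3, none needed for 1x1
    return nn.Sequential(
        nn.Conv2d(cin, cout, kernel, padding=(kernel - 1) // 2, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class Branch(nn.Module):
    """Patch- and layer-specific localisation network producing a spatial
    sparsemax attention map with the same height/width as its input."""

    def __init__(self, in_channels: int = 3, channels: int = 16, *,
                 rng: np.random.Generator):
        super().__init__()
        c = channels
        self.path1 = _conv_bn_relu(in_channels, c, 1, rng)
        self.path2 = nn.Sequential(
            _conv_bn_relu(in_channels, c, 1, rng), _conv_bn_relu(c, c, 3, rng)
        )
        self.path3 = nn.Sequential(
            _conv_bn_relu(in_channels, c, 1, rng),
            _conv_bn_relu(c, c, 3, rng),
            _conv_bn_relu(c, c, 3, rng),
        )
        self.path4 = nn.Sequential(
            _conv_bn_relu(in_channels, c, 1, rng),
            _conv_bn_relu(c, c, 3, rng),
            _conv_bn_relu(c, c, 3, rng),
            _conv_bn_relu(c, c, 3, rng),
        )
        self.path5 = nn.Sequential(
            nn.MaxPool2d(3, stride=1, padding=1),
            _conv_bn_relu(in_channels, c, 1, rng),
        )
        # near-zero projection => near-uniform initial attention (no zoom)
        self.proj = nn.Conv2d(5 * c, 1, 1, rng=rng)
        self.proj.weight.data *= 1e-3

    def forward(self, x: Tensor) -> Tensor:
        """Attention map of shape (B, H, W) summing to one per sample."""
        feats = concatenate(
            [self.path1(x), self.path2(x), self.path3(x),
             self.path4(x), self.path5(x)],
            axis=1,
        )
        logits = self.proj(feats)  # (B, 1, H, W)
        B, _, H, W = logits.shape
        flat = logits.reshape(B, H * W)
        return t_sparsemax(flat, axis=-1).reshape(B, H, W)


def localize(view: np.ndarray, weights: Branch) -> np.ndarray:
    """Run one Branch on a single H x W x 3 view (0-255) and return its map."""
    view = np.asarray(view)
    if view.ndim != 3 or view.shape[2] != 3:
        raise ContractError(f"expected H x W x 3 view, got {view.shape}")
    x = Tensor(view.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    was_training = weights.training
    weights.eval()
    out = weights(x).data[0]
    weights.train(was_training)
    return out


def _cell_centers(n: int) -> np.ndarray:
    """Normalised cell-centre coordinates (2i+1)/n - 1 (mass never at +-1)."""
    return (2.0 * np.arange(n) + 1.0) / n - 1.0


def infer_affine_params_t(pmap: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Raw (s, tx, ty) from a batch of attention maps (B, H, W), on-graph."""
    B, H, W = pmap.shape
    ux = _cell_centers(W)
    uy = _cell_centers(H)
    px = pmap.sum(axis=1)  # (B, W) marginal over rows
    py = pmap.sum(axis=2)  # (B, H)
    tx = px @ Tensor(ux)
    ty = py @ Tensor(uy)
    dev_x = (Tensor(ux[None, :]) - tx.reshape(B, 1)).abs()
    dev_y = (Tensor(uy[None, :]) - ty.reshape(B, 1)).abs()
    s = (px * dev_x).sum(axis=1) + (py * dev_y).sum(axis=1)
    return s, tx, ty


def infer_affine_params(pmap: np.ndarray) -> tuple[float, float, float]:
    """Raw (s_raw, tx_raw, ty_raw) from a single normalised attention map."""
    pmap = np.asarray(pmap, dtype=np.float64)
    if pmap.ndim != 2:
        raise ContractError("attention map must be 2-D")
    if abs(pmap.sum() - 1.0) > 1e-6 or (pmap < 0).any():
        raise ContractError("attention map must be a probability mass function")
    s, tx, ty = infer_affine_params_t(Tensor(pmap[None]))
    return float(s.data[0]), float(tx.data[0]), float(ty.data[0])


def constrain_params_t(s_raw: Tensor, tx_raw: Tensor, ty_raw: Tensor):
    """Apply the floor/tanh constraints on-graph."""
    return (
        t_maximum(astensor(s_raw), S_FLOOR),
        astensor(tx_raw).tanh(),
        astensor(ty_raw).tanh(),
    )


def constrain_params(s_raw: float, tx_raw: float, ty_raw: float) -> AffineParams:
    """s = max(s, 0.05); tx = tanh(tx); ty = tanh(ty)."""
    return AffineParams(
        s=max(float(s_raw), S_FLOOR),
        tx=float(np.tanh(tx_raw)),
        ty=float(np.tanh(ty_raw)),
    )


def make_grid(theta, out_side: int) -> np.ndarray:
    """Sample points (out, out, 2) mapping the base meshgrid through theta:
    ``x = s*gx + tx``, ``y = s*gy + ty``."""
    if isinstance(theta, (tuple, list)):
        s, tx, ty = theta
    else:
        s, tx, ty = theta.s, theta.tx, theta.ty
    gx, gy = base_grid(out_side)
    return np.stack([s * gx + tx, s * gy + ty], axis=-1)


def bilinear_sample(image: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Plain bilinear sampling of an H x W x C image on ``grid`` (out,out,2)."""
    image = np.asarray(image, dtype=np.float64)
    chw = image.transpose(2, 0, 1)
    x = grid[..., 0].ravel()
    y = grid[..., 1].ravel()
    vals = bilinear_eval(chw, x, y)
    out_side = grid.shape[0]
    return vals.reshape(-1, out_side, grid.shape[1]).transpose(1, 2, 0)


def linearized_sample(image: np.ndarray, grid: np.ndarray, k_aux: int = 8,
                      noise_sd: float | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Linearized multi-sampling of an H x W x C image on ``grid``.

    ``noise_sd`` defaults to ``1/out_side`` (jitter on the scale of one
    output cell); the zero-noise limit reduces to bilinear interpolation.
    """
    image = np.asarray(image, dtype=np.float64)
    out_side = grid.shape[0]
    if noise_sd is None:
        noise_sd = 1.0 / out_side
    if noise_sd == 0:
        return bilinear_sample(image, grid)
    if rng is None:
        rng = np.random.default_rng()
    chw = image.transpose(2, 0, 1)
    x = grid[..., 0].ravel()
    y = grid[..., 1].ravel()
    vals, _, _ = linearized_eval(chw, x, y, k_aux=k_aux, noise_sd=noise_sd, rng=rng)
    return vals.reshape(-1, out_side, grid.shape[1]).transpose(1, 2, 0)
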