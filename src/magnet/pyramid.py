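"""Multi-resolution pyramid abstraction.

A :class:`PyramidImage` stores one RGB raster per magnification level, with
level 0 at full resolution and each subsequent level halving both
dimensions (``ceil`` rounding).  Region reads select the level dynamically
from the requested extent, so a deeply zoomed view automatically touches a
finer raster than a whole-slide overview.

Coordinates live in continuous level-0 pixel space (origin top-left, y
down).  A :class:`ViewFrame` is a centre plus half-extents in that space;
nested attention decisions compose frames via :func:`compose_frames`.

On-disk layout: a directory with ``level_<k>.png`` per level and a
``meta.json`` holding ``h0``, ``w0`` and ``mmax``.  Multi-page pyramidal
TIFF (page k = level k) is supported read-only as a bridge to standard
tooling.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FormatError, InvalidRequestError
from .preprocess import resize_pad

__all__ = [
    "LevelQuery",
    "PyramidImage",
    "ViewFrame",
    "build_pyramid",
    "compose_frames",
    "level_query",
    "load_pyramid",
    "load_tiff_pyramid",
    "read_region",
    "root_frame",
    "save_pyramid",
    "select_level",
]

DOWNSAMPLE_FACTOR = 2


def _level_dims(h0: int, w0: int, k: int) -> tuple[int, int]:
    f = DOWNSAMPLE_FACTOR**k
    return math.ceil(h0 / f), math.ceil(w0 / f)


@dataclass
class PyramidImage:
    """An RGB raster stack; ``levels[0]`` is full resolution."""

    levels: list
    h0: int
    w0: int
    mmax: int
    downsample_factor: int = DOWNSAMPLE_FACTOR

    def __post_init__(self):
        if self.mmax != len(self.levels) or self.mmax < 1:
            raise FormatError("mmax must equal the number of stored levels (>= 1)")
        for k, lvl in enumerate(self.levels):
            lvl = np.asarray(lvl)
            if lvl.ndim != 3 or lvl.shape[2] != 3:
                raise FormatError(f"level {k} is not an H x W x 3 raster")
            expect = _level_dims(self.h0, self.w0, k)
            if lvl.shape[:2] != expect:
                raise FormatError(
                    f"level {k} has shape {lvl.shape[:2]}, expected {expect}"
                )

    def level(self, k: int) -> np.ndarray:
        return self.levels[k]


@dataclass(frozen=True)
class ViewFrame:
    """Centre + half-extents in continuous level-0 pixel coordinates."""

    center_x: float
    center_y: float
    half_w: float
    half_h: float
    depth: int = 0

    @property
    def hc(self) -> float:
        return 2.0 * self.half_h

    @property
    def wc(self) -> float:
        return 2.0 * self.half_w

    def contains(self, x: float, y: float) -> bool:
        return (
            abs(x - self.center_x) <= self.half_w
            and abs(y - self.center_y) <= self.half_h
        )


@dataclass(frozen=True)
class LevelQuery:
    """The level-selection intermediate quantities for one region request."""

    Rh: int
    Rw: int
    R: int
    m: int


def root_frame(pyramid: PyramidImage) -> ViewFrame:
    """The frame covering the whole slide."""
    return ViewFrame(
        center_x=pyramid.w0 / 2.0,
        center_y=pyramid.h0 / 2.0,
        half_w=pyramid.w0 / 2.0,
        half_h=pyramid.h0 / 2.0,
        depth=0,
    )


def _floor_log2_ratio(num: float, den: float) -> int:
    """floor(log2(num/den)) robust against floating-point error at powers of 2."""
    r = num / den
    R = int(math.floor(math.log2(r)))
    while 2.0 ** (R + 1) <= r * (1.0 + 1e-12):
        R += 1
    while 2.0**R > r * (1.0 + 1e-12):
        R -= 1
    return R


def level_query(h0: float, w0: float, hc: float, wc: float, mmax: int) -> LevelQuery:
    """Compute Rh, Rw, R and the clamped level index m for a region request."""
    if mmax < 1:
        raise InvalidRequestError("mmax must be >= 1")
    if hc <= 0 or wc <= 0:
        raise InvalidRequestError("requested extents must be positive")
    if h0 < 1 or w0 < 1:
        raise InvalidRequestError("slide dimensions must be >= 1")
    if hc > h0 or wc > w0:
        raise InvalidRequestError(
            f"requested extent ({hc} x {wc}) exceeds the slide ({h0} x {w0})"
        )
    Rh = _floor_log2_ratio(h0, hc)
    Rw = _floor_log2_ratio(w0, wc)
    R = max(Rh, Rw)
    # The printed formula yields m = mmax for a full-slide request; the level
    # index is clamped to the stored range [0, mmax - 1].
    m = min(max(mmax - R, 0), mmax - 1)
    return LevelQuery(Rh=Rh, Rw=Rw, R=R, m=m)


def select_level(h0: float, w0: float, hc: float, wc: float, mmax: int) -> int:
    """Magnification level for a requested extent: m = max(mmax - R, 0), clamped."""
    return level_query(h0, w0, hc, wc, mmax).m


def compose_frames(parent: ViewFrame, theta) -> ViewFrame:
    """Child frame of ``parent`` under affine parameters ``(s, tx, ty)``.

    ``theta`` may be an :class:`~magnet.attention.AffineParams` or any object
    with ``s``, ``tx``, ``ty`` attributes (or a 3-tuple).  Translations are
    expressed in the parent's normalised view coordinates, so the child
    centre moves by ``t * half_extent`` and extents scale by ``s``.
    """
    if isinstance(theta, (tuple, list)):
        s, tx, ty = theta
    else:
        s, tx, ty = theta.s, theta.tx, theta.ty
    return ViewFrame(
        center_x=parent.center_x + float(tx) * parent.half_w,
        center_y=parent.center_y + float(ty) * parent.half_h,
        half_w=float(s) * parent.half_w,
        half_h=float(s) * parent.half_h,
        depth=parent.depth + 1,
    )


def read_region(pyramid: PyramidImage, frame: ViewFrame, out_side: int) -> np.ndarray:
    """Read the frame's rectangle at the dynamically selected level.

    The level is chosen from the frame's extent (clipped to the slide), the
    level-m window is cropped with black fill outside the raster, resized
    with bilinear interpolation so the longer side equals ``out_side``, and
    padded symmetrically with black to ``out_side`` x ``out_side``.  A frame
    entirely outside the slide yields an all-black image and a warning.
    """
    if out_side < 2:
        raise InvalidRequestError("out_side must be >= 2")
    x0, x1 = frame.center_x - frame.half_w, frame.center_x + frame.half_w
    y0, y1 = frame.center_y - frame.half_h, frame.center_y + frame.half_h
    if x1 <= 0 or y1 <= 0 or x0 >= pyramid.w0 or y0 >= pyramid.h0:
        warnings.warn(
            "frame lies entirely outside the slide; returning black",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros((out_side, out_side, 3), dtype=np.uint8)
    hc = min(max(frame.hc, 1.0), float(pyramid.h0))
    wc = min(max(frame.wc, 1.0), float(pyramid.w0))
    m = select_level(pyramid.h0, pyramid.w0, hc, wc, pyramid.mmax)
    scale = float(DOWNSAMPLE_FACTOR**m)
    raster = pyramid.level(m)
    Hm, Wm = raster.shape[:2]
    xi0, xi1 = int(round(x0 / scale)), int(round(x1 / scale))
    yi0, yi1 = int(round(y0 / scale)), int(round(y1 / scale))
    xi1, yi1 = max(xi1, xi0 + 1), max(yi1, yi0 + 1)
    window = np.zeros((yi1 - yi0, xi1 - xi0, 3), dtype=raster.dtype)
    sx0, sx1 = max(xi0, 0), min(xi1, Wm)
    sy0, sy1 = max(yi0, 0), min(yi1, Hm)
    if sx1 > sx0 and sy1 > sy0:
        window[sy0 - yi0 : sy1 - yi0, sx0 - xi0 : sx1 - xi0] = raster[
            sy0:sy1, sx0:sx1
        ]
    return resize_pad(window, out_side)


# ---------------------------------------------------------------------------
# construction and persistence
# ---------------------------------------------------------------------------


def build_pyramid(level0: np.ndarray, mmax: int) -> PyramidImage:
    """Build a pyramid from a level-0 raster by successive 2x area-mean
    (box) downsampling."""
    level0 = np.asarray(level0)
    if level0.ndim != 3 or level0.shape[2] != 3:
        raise FormatError("level-0 raster must be H x W x 3")
    if mmax < 1:
        raise FormatError("mmax must be >= 1")
    h0, w0 = level0.shape[:2]
    levels = [level0.astype(np.uint8, copy=False)]
    for k in range(1, mmax):
        prev = levels[-1]
        h, w = prev.shape[:2]
        hk, wk = _level_dims(h0, w0, k)
        if h % 2 == 0 and w % 2 == 0:
            nxt = (
                prev.astype(np.float32)
                .reshape(h // 2, 2, w // 2, 2, 3)
                .mean(axis=(1, 3))
            )
            nxt = np.clip(np.rint(nxt), 0, 255).astype(np.uint8)
        else:
            nxt = np.asarray(Image.fromarray(prev).resize((wk, hk), Image.BOX))
        levels.append(nxt)
    return PyramidImage(levels=levels, h0=h0, w0=w0, mmax=mmax)


def save_pyramid(pyramid: PyramidImage, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, lvl in enumerate(pyramid.levels):
        Image.fromarray(np.asarray(lvl, dtype=np.uint8)).save(
            path / f"level_{k}.png"
        )
    meta = {"h0": int(pyramid.h0), "w0": int(pyramid.w0), "mmax": int(pyramid.mmax)}
    (path / "meta.json").write_text(json.dumps(meta))
    return path


def load_pyramid(path) -> PyramidImage:
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FormatError(f"{path} is not a pyramid directory (no meta.json)")
    meta = json.loads(meta_file.read_text())
    levels = []
    for k in range(meta["mmax"]):
        f = path / f"level_{k}.png"
        if not f.exists():
            raise FormatError(f"missing raster {f}")
        levels.append(np.asarray(Image.open(f).convert("RGB")))
    return PyramidImage(
        levels=levels, h0=meta["h0"], w0=meta["w0"], mmax=meta["mmax"]
    )


def load_tiff_pyramid(path) -> PyramidImage:
    """Read a multi-page pyramidal TIFF where page k is the level-k raster."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise FormatError(f"{path} contains no pages")
    pages = [
        np.repeat(p[:, :, None], 3, axis=2) if p.ndim == 2 else p[..., :3]
        for p in pages
    ]
    h0, w0 = pages[0].shape[:2]
    return PyramidImage(levels=pages, h0=h0, w0=w0, mmax=len(pages))


_VIEW_TRANSFORMS = {
    "none": lambda a: a,
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1],
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
}


def transformed(pyramid: PyramidImage, code: str) -> PyramidImage:
    """A pyramid with every level raster dihedrally transformed (for
    train-time augmentation); rotations require a square slide.

    Levels are numpy views (no copies): region reads copy out of them
    anyway, so augmentation costs nothing per batch.
    """
    try:
        op = _VIEW_TRANSFORMS[code]
    except KeyError:
        raise FormatError(f"unknown augmentation code {code!r}") from None
    new_levels = [op(lvl) for lvl in pyramid.levels]
    h0, w0 = new_levels[0].shape[:2]
    return replace(pyramid, levels=new_levels, h0=h0, w0=w0)
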