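"""Synthetic labelled pyramids with planted multi-scale lesions.

Each slide is rendered at level 0 as a white background carrying a
pink-textured tissue blob, optional grey scanning smudges, and — for
positive slides — a small purple high-frequency "lesion" disc placed fully
inside the tissue.  Lower levels are obtained by 2x area-mean downsampling.

Lesion diameters are controlled relative to the slide: ``macro`` lesions
span about 1/8 of the level-0 side and are visible in a whole-slide
thumbnail, while ``micro`` lesions span about 1/64 — smaller than one cell
of the 56 x 56 root view, so detecting them requires zooming in.

All randomness for a slide is drawn in a fixed order that does not depend
on the label; the lesion raster is painted last and only when the label is
positive, so the positive and negative renders of the same seed differ
exactly by the lesion pixels.

Colour design ties into the grey filter: tissue and lesion colours keep a
per-pixel channel spread of at least 15 (they survive filtering), while
smudges are grey by construction (spread < 15) and are provably removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import GenerationError, InvalidRequestError
from .pyramid import PyramidImage, build_pyramid, save_pyramid

__all__ = [
    "LESION_DIAMETER_FRAC",
    "SlideSpec",
    "SlideTruth",
    "generate_dataset",
    "generate_slide",
]

LESION_DIAMETER_FRAC = {"macro": 1.0 / 8.0, "micro": 1.0 / 64.0}

_TISSUE_RGB = np.array([228.0, 168.0, 198.0])  # pink-ish, channel spread 60
_NODULE_RGB = np.array([188.0, 122.0, 158.0])  # darker pink, channel spread 66
_LESION_RGB = np.array([110.0, 35.0, 205.0])  # saturated purple, spread 170


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide."""

    level0_side: int = 2048
    mmax: int = 6
    tissue_fraction: float = 0.4
    lesion_scale: str = "macro"
    artifact_rate: float = 1.5
    label: int = 1

    def __post_init__(self):
        if self.lesion_scale not in LESION_DIAMETER_FRAC:
            raise InvalidRequestError(
                f"lesion_scale must be one of {sorted(LESION_DIAMETER_FRAC)}"
            )
        if self.label not in (0, 1):
            raise InvalidRequestError("label must be 0 or 1")
        if not 0.05 <= self.tissue_fraction <= 0.9:
            raise InvalidRequestError("tissue_fraction out of range")


@dataclass
class SlideTruth:
    """Ground truth for a generated slide; lesion fields present iff label=1."""

    label: int
    lesion_center: tuple | None = None
    lesion_radius: float | None = None
    lesion_scale: str | None = None


def _tissue_mask(side: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    cx = side * (0.5 + rng.uniform(-0.05, 0.05))
    cy = side * (0.5 + rng.uniform(-0.05, 0.05))
    aspect = rng.uniform(0.75, 1.33)
    base = side * np.sqrt(fraction / np.pi)
    a, b = base * np.sqrt(aspect), base / np.sqrt(aspect)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    ys, xs = np.mgrid[0:side, 0:side].astype(np.float32)
    dx, dy = xs - cx, ys - cy
    ang = np.arctan2(dy, dx)
    wobble = 1.0 + 0.12 * np.sin(3 * ang + ph1) + 0.08 * np.sin(5 * ang + ph2)
    rr = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    return rr <= wobble


def generate_slide(spec: SlideSpec, seed) -> tuple[PyramidImage, SlideTruth]:
    """Render one slide deterministically from ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    side = spec.level0_side
    canvas = np.full((side, side, 3), 255.0, dtype=np.float32)

    # 1. tissue blob with smooth colour texture (low-frequency noise is
    #    rendered at quarter resolution and upsampled — identical character,
    #    16x cheaper than filtering at full resolution)
    tissue = _tissue_mask(side, spec.tissue_fraction, rng)
    small = max(side // 4, 1)
    field = rng.standard_normal((small, small)).astype(np.float32)
    field = gaussian_filter(field, sigma=max(side / 1024.0, 0.5))
    field *= 1.2  # smoothed noise has small variance; rescale to ~N(0, 0.1)
    from PIL import Image

    field = np.asarray(
        Image.fromarray(field, mode="F").resize((side, side), Image.BILINEAR)
    )
    # lightness-only texture: the hue stays on the tissue colour line, so a
    # hue shift (the lesion) is never mimicked by texture variation
    texture = np.clip(
        _TISSUE_RGB * (1.0 + 0.12 * field)[..., None], 0, 255
    ).astype(np.float32)
    canvas[tissue] = texture[tissue]

    # 2. grey smudges (channel spread < 15 so the grey filter removes them)
    n_artifacts = int(rng.poisson(spec.artifact_rate))
    ys, xs = np.mgrid[0:side, 0:side].astype(np.float32)
    for _ in range(n_artifacts):
        ax, ay = rng.uniform(0, side, size=2)
        ar = rng.uniform(side / 64.0, side / 16.0)
        grey = rng.uniform(120.0, 210.0)
        jitter = rng.uniform(-6.0, 6.0, size=3)
        mask = (xs - ax) ** 2 + (ys - ay) ** 2 <= ar**2
        canvas[mask] = np.clip(grey + jitter, 0, 255)

    # 3. nodule + lesion placement.  Every slide carries one darker "nodule"
    #    structure (visible in the whole-slide view, label-independent),
    #    mimicking the anatomical context a metastasis sits in; positive
    #    slides additionally get the purple lesion disc at its centre, so
    #    the label-defining evidence only resolves at higher magnification.
    #    All draws happen regardless of the label so the random stream stays
    #    label-independent.
    radius = side * LESION_DIAMETER_FRAC[spec.lesion_scale] / 2.0
    nodule_radius = min(4.0 * radius, side / 16.0)
    center = None
    rows, cols = np.nonzero(tissue)
    if rows.size == 0:
        raise GenerationError("tissue mask is empty")
    for _ in range(200):
        i = int(rng.integers(rows.size))
        ly, lx = float(rows[i]), float(cols[i])
        r_int = int(np.ceil(nodule_radius))
        y0, y1 = int(ly) - r_int, int(ly) + r_int + 1
        x0, x1 = int(lx) - r_int, int(lx) + r_int + 1
        if y0 < 0 or x0 < 0 or y1 > side or x1 > side:
            continue
        box = tissue[y0:y1, x0:x1]
        by, bx = np.mgrid[y0:y1, x0:x1]
        nodule_disc = (bx - lx) ** 2 + (by - ly) ** 2 <= nodule_radius**2
        if np.all(box[nodule_disc]):
            center = (lx, ly)
            break
    if center is None:
        raise GenerationError(
            "could not place the lesion inside tissue after 200 attempts"
        )
    lesion_noise = rng.uniform(-25.0, 25.0, size=(y1 - y0, x1 - x0, 3)).astype(
        np.float32
    )

    patch = canvas[y0:y1, x0:x1]
    patch[nodule_disc] = np.clip(
        _NODULE_RGB * (1.0 + 0.12 * field[y0:y1, x0:x1, None]), 0, 255
    )[nodule_disc]
    if spec.label == 1:
        lesion_disc = (bx - lx) ** 2 + (by - ly) ** 2 <= radius**2
        patch[lesion_disc] = np.clip(_LESION_RGB + lesion_noise, 0, 255)[
            lesion_disc
        ]
        truth = SlideTruth(
            label=1,
            lesion_center=center,
            lesion_radius=radius,
            lesion_scale=spec.lesion_scale,
        )
    else:
        truth = SlideTruth(label=0)

    pyramid = build_pyramid(np.clip(np.rint(canvas), 0, 255).astype(np.uint8),
                            spec.mmax)
    return pyramid, truth


def generate_dataset(
    n: int,
    out_dir,
    seed: int,
    *,
    level0_side: int = 2048,
    mmax: int = 6,
    tissue_fraction: float = 0.4,
    lesion_scale: str = "macro",
    artifact_rate: float = 1.5,
    split: tuple = (0.8, 0.2),
    split_names: tuple = ("train", "val", "test"),
) -> pd.DataFrame:
    """Generate ``n`` slides with balanced labels (+-1) and write a manifest.

    Slide seeds fan out from the master ``seed`` via ``SeedSequence.spawn``;
    re-running with the same arguments reproduces every pixel and the
    manifest bit for bit.  The manifest CSV columns are ``path``, ``label``,
    ``lesion_x``, ``lesion_y``, ``lesion_r``, ``lesion_scale``, ``split``.
    """
    if n < 2:
        raise InvalidRequestError("need at least two slides")
    if abs(sum(split) - 1.0) > 1e-9 or len(split) > len(split_names):
        raise InvalidRequestError("split proportions must sum to 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    slide_seeds = master.spawn(n)
    order_rng = np.random.default_rng(master.spawn(1)[0])

    labels = np.array([1] * (n // 2 + n % 2) + [0] * (n // 2))
    order_rng.shuffle(labels)

    # stratified split assignment so both classes appear in every split
    splits = np.empty(n, dtype=object)
    for label in (0, 1):
        idx = np.nonzero(labels == label)[0]
        order_rng.shuffle(idx)
        exact = np.asarray(split) * idx.size
        counts = np.floor(exact).astype(int)
        # hand remainders to the splits with the largest fractional parts
        for k in np.argsort(-(exact - counts))[: idx.size - counts.sum()]:
            counts[k] += 1
        start = 0
        for name, cnt in zip(split_names, counts):
            splits[idx[start : start + cnt]] = name
            start += cnt

    rows = []
    for i in range(n):
        spec = SlideSpec(
            level0_side=level0_side,
            mmax=mmax,
            tissue_fraction=tissue_fraction,
            lesion_scale=lesion_scale,
            artifact_rate=artifact_rate,
            label=int(labels[i]),
        )
        pyramid, truth = generate_slide(spec, slide_seeds[i])
        slide_dir = out_dir / f"slide_{i:04d}"
        save_pyramid(pyramid, slide_dir)
        rows.append(
            {
                "path": slide_dir.name,
                "label": truth.label,
                "lesion_x": truth.lesion_center[0] if truth.lesion_center else np.nan,
                "lesion_y": truth.lesion_center[1] if truth.lesion_center else np.nan,
                "lesion_r": truth.lesion_radius if truth.lesion_radius else np.nan,
                "lesion_scale": truth.lesion_scale if truth.label else "none",
                "split": splits[i],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
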