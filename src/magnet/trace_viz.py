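"""Visualisation of a forward-pass patch trace.

Each magnifying layer gets one panel row; every materialised patch is shown
re-read from the pyramid at its recorded frame, labelled with its
hierarchical name, with the outlines of its children drawn in slot colours
(red / blue / green / ...).  Background (grey-filtered) pixels are shown
white, purely for visualisation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .errors import InvalidRequestError
from .model import PatchTrace
from .preprocess import grey_filter
from .pyramid import PyramidImage, read_region

__all__ = ["render_trace"]

_SLOT_COLOURS = ["red", "blue", "green", "orange", "purple"]


def render_trace(trace: PatchTrace, pyramid: PyramidImage, out_path) -> Path:
    """Write a panel figure of every patch in ``trace`` to ``out_path`` (PNG)."""
    if len(trace) == 0:
        raise InvalidRequestError("cannot render an empty trace")
    out_path = Path(out_path)
    layers = sorted({e.layer for e in trace.entries})
    by_layer = {l: [e for e in trace.entries if e.layer == l] for l in layers}
    ncols = max(len(v) for v in by_layer.values())
    nrows = len(layers)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(1.6 * ncols, 1.9 * nrows), squeeze=False
    )
    children_of: dict[str, list] = {}
    for e in trace.entries:
        if e.parent is not None:
            children_of.setdefault(e.parent, []).append(e)
    for r, layer in enumerate(layers):
        for c in range(ncols):
            ax = axes[r][c]
            ax.axis("off")
            if c >= len(by_layer[layer]):
                continue
            e = by_layer[layer][c]
            img = grey_filter(read_region(pyramid, e.frame, e.resolution))
            shown = img.copy()
            shown[(img == 0).all(axis=2)] = 255  # background white for display
            ax.imshow(shown)
            ax.set_title(e.name, fontsize=7)
            side = e.resolution
            for child in children_of.get(e.name, []):
                th = child.theta
                cx = (th.tx + 1.0) / 2.0 * side
                cy = (th.ty + 1.0) / 2.0 * side
                half = th.s * side / 2.0
                ax.add_patch(
                    Rectangle(
                        (cx - half, cy - half), 2 * half, 2 * half,
                        fill=False, linewidth=0.8,
                        edgecolor=_SLOT_COLOURS[
                            (child.slot - 1) % len(_SLOT_COLOURS)
                        ],
                    )
                )
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
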