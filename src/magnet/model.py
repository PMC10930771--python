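"""The magnifying network: recursive attention layers over an image pyramid.

One forward pass starts from a 56 x 56 whole-slide view and repeatedly
(i) localises regions of interest with patch-specific Branches,
(ii) composes the inferred affine crop with the accumulated view frame, and
(iii) materialises each child patch by sampling the affine grid from a
higher-fidelity source view I' freshly read from the pyramid at the
dynamically selected magnification level (112 x 112 between magnifying
layers, 224 x 224 into the classification layer).

Child pixels therefore come from the differentiable sampler — so the crop
parameters receive gradients — while each view's I' is a fresh pyramid read
that restores fidelity lost upstream.  The optional frozen patch pins the
first slot of layer 2 to the identity transform so one child always covers
the whole parent view.

Final-layer patches feed a CNN backbone whose per-patch features run
through a GRU and a two-layer fully-connected head into a slide-level
probability.  Auxiliary classifiers on the layer-1 and layer-3 patches
(layer L when the network is shallower) provide the intermediate
supervision used by the paradoxical loss.

Every materialised image is recorded in a :class:`PatchTrace` under a
hierarchical name (I1, I11, I131, ...) encoding its extraction path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import prod
from typing import Callable

import numpy as np

from . import nn
from ._sampling import affine_sample
from ._tensor import Tensor, concatenate, stack
from .attention import (
    AffineParams,
    Branch,
    constrain_params_t,
    infer_affine_params_t,
)
from .errors import ContractError, InvalidRequestError
from .preprocess import GREY_TAU_DEFAULT, grey_filter
from .pyramid import (
    PyramidImage,
    ViewFrame,
    compose_frames,
    read_region,
    root_frame,
    select_level,
)

__all__ = [
    "ForwardResult",
    "MagNet",
    "MagNetConfig",
    "PatchBudget",
    "PatchTrace",
    "TraceEntry",
    "auxiliary_predict",
    "count_patches",
    "load_checkpoint",
    "save_checkpoint",
]


@dataclass
class MagNetConfig:
    """Architecture + sampler settings for one magnifying network."""

    layers: int = 3
    patches: tuple = (3, 2, 3)
    frozen_patch: bool = True
    in_side: int = 56
    hi_side: int = 112
    final_side: int = 224
    backbone: str = "small-cnn"
    branch_channels: int = 16
    backbone_channels: tuple = (16, 32, 64, 128)
    aux_channels: tuple | None = None
    gru_hidden: int = 256
    head_sizes: tuple = (512, 256)
    k_aux: int = 8
    noise_sd: float | None = None  # None -> 1/out_side at sampling time
    grey_tau: float = GREY_TAU_DEFAULT
    # share the classification backbone with the deepest auxiliary
    # classifier (desk-scale stand-in for pretrained features; only applies
    # when that auxiliary sits on the final layer)
    share_aux_backbone: bool = False

    def __post_init__(self):
        self.patches = tuple(int(p) for p in self.patches)
        if self.layers < 1:
            raise InvalidRequestError("need at least one magnifying layer")
        if len(self.patches) != self.layers:
            raise InvalidRequestError("patches must list one count per layer")
        if any(p < 1 for p in self.patches):
            raise InvalidRequestError("all per-layer patch counts must be >= 1")

    @property
    def aux_layers(self) -> tuple:
        """Layers feeding the auxiliary classifiers (1 and 3, or 1 and L)."""
        if self.layers == 1:
            return (1,)
        return (1, 3 if self.layers >= 3 else self.layers)


@dataclass(frozen=True)
class PatchBudget:
    """Closed-form patch/pixel accounting for a configuration."""

    n_small: int
    n_large: int
    pixels_total: int

    @property
    def total(self) -> int:
        return self.n_small + self.n_large


def count_patches(config: MagNetConfig) -> PatchBudget:
    """Images materialised per slide: the root input plus every extracted ROI.

    ``n_small`` counts the 56 x 56 images (root + all non-final-layer
    patches); ``n_large`` the final-layer patches at 224 x 224.
    """
    P = config.patches
    n_small = 1 + sum(prod(P[: l + 1]) for l in range(config.layers - 1))
    n_large = prod(P)
    pixels = (
        n_small * config.in_side**2 * 3 + n_large * config.final_side**2 * 3
    )
    return PatchBudget(n_small=n_small, n_large=n_large, pixels_total=pixels)


@dataclass
class TraceEntry:
    name: str
    parent: str | None
    layer: int
    slot: int | None
    theta: AffineParams | None
    level: int
    frame: ViewFrame
    resolution: int


@dataclass
class PatchTrace:
    entries: list = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def by_name(self) -> dict:
        return {e.name: e for e in self.entries}

    def at_resolution(self, side: int) -> list:
        return [e for e in self.entries if e.resolution == side]

    def leaves(self) -> list:
        names = {e.name for e in self.entries}
        return [e for e in self.entries if not any(
            n != e.name and n.startswith(e.name) for n in names
        )]


@dataclass
class ForwardResult:
    y_hat: object  # Tensor (B,) during batched calls, float for single slides
    aux: dict  # layer index -> class-1 probability (Tensor (B,) / float)
    traces: list  # list[PatchTrace], one per slide


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------


class SmallCNN(nn.Module):
    """Stride-2 conv/BN/ReLU blocks + global average pooling.

    The desk-scale stand-in for the ImageNet-pretrained backbones: those
    require externally downloaded weights and a GPU budget, so they are
    accepted as identifiers but must be registered by the user.
    """

    def __init__(self, channels=(16, 32, 64, 128), in_ch: int = 3, *,
                 rng: np.random.Generator):
        super().__init__()
        # full-resolution 1x1 stem: per-pixel (colour) features are formed
        # before any downsampling, so a salient region spanning only a few
        # pixels is detected rather than averaged away.  Half of the stem is
        # initialised with classical colour-opponent filters (+-(R-G),
        # +-(B-G), +-(R-B)) so hue contrasts are linearly exposed from the
        # first step regardless of the random draw; the rest is random.
        stem_ch = channels[0]
        stem = nn.Conv2d(in_ch, stem_ch, 1, rng=rng)
        if in_ch == 3:
            opponent = np.array(
                [
                    [1, -1, 0], [-1, 1, 0],
                    [0, -1, 1], [0, 1, -1],
                    [1, 0, -1], [-1, 0, 1],
                ],
                dtype=np.float32,
            )
            k = min(stem_ch // 2, len(opponent))
            stem.weight.data[:k] = opponent[:k].reshape(k, 3, 1, 1)
        blocks = [stem, nn.BatchNorm2d(stem_ch), nn.ReLU()]
        prev = stem_ch
        for c in channels:
            # non-overlapping 2x2 stride-2 convs: im2col is a cheap reshape
            blocks += [
                nn.Conv2d(prev, c, 2, stride=2, rng=rng),
                nn.BatchNorm2d(c),
                nn.ReLU(),
            ]
            prev = c
        blocks += [  # one 3x3 mixer at the coarsest resolution
            nn.Conv2d(prev, prev, 3, padding=1, rng=rng),
            nn.BatchNorm2d(prev),
            nn.ReLU(),
        ]
        self.body = nn.Sequential(*blocks)
        self.feature_dim = 2 * prev

    def forward(self, x: Tensor) -> Tensor:
        # average + max pooling: the max path lets a single strongly
        # activated location (a small salient region) survive the pooling
        feats = self.body(x)
        return concatenate([feats.mean(axis=(2, 3)), feats.amax(axis=(2, 3))],
                           axis=1)


_BACKBONES: dict[str, Callable] = {}


def register_backbone(name: str, factory: Callable):
    _BACKBONES[name] = factory


def make_backbone(name: str, channels, rng) -> nn.Module:
    if name == "small-cnn":
        return SmallCNN(channels=channels, rng=rng)
    if name in _BACKBONES:
        return _BACKBONES[name](channels=channels, rng=rng)
    if name in ("inception-v3", "resnet-18"):
        raise NotImplementedError(
            f"backbone {name!r} needs pretrained weights and a deep-learning "
            "runtime; register a factory with register_backbone() to use it"
        )
    raise InvalidRequestError(f"unknown backbone {name!r}")


class _AuxClassifier(nn.Module):
    """Per-patch CNN + linear head, averaged into one slide probability."""

    def __init__(self, channels, rng, backbone: nn.Module | None = None):
        super().__init__()
        # a shared backbone stands in for the pretrained feature extractors
        # of the reference configuration: the auxiliary loss then supervises
        # the classification features directly
        self.backbone = backbone or SmallCNN(channels=channels, rng=rng)
        self.head = nn.Linear(self.backbone.feature_dim, 1, rng=rng)

    def forward(self, patches: list) -> Tensor:
        probs = [
            self.head(self.backbone(p)).sigmoid().reshape(-1) for p in patches
        ]
        return sum(probs[1:], probs[0]) / float(len(probs))


def auxiliary_predict(patches: list, weights: _AuxClassifier, y) -> np.ndarray:
    """Slide-level probability of the *true* class from one layer's patches.

    ``patches`` are H x W x 3 arrays (0-255) from a single slide; per-patch
    class-1 probabilities are averaged and complemented for negatives.
    """
    if not patches:
        raise ContractError("auxiliary classifier received no patches")
    tensors = [
        Tensor(np.asarray(p, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0)
        for p in patches
    ]
    was_training = weights.training
    weights.eval()
    p = float(weights(tensors).data[0])
    weights.train(was_training)
    return p if y == 1 else 1.0 - p


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class _ViewBatch:
    """One view slot across a batch of slides."""

    __slots__ = ("frames", "imgs", "names", "src_levels")

    def __init__(self, frames, imgs, names, src_levels):
        self.frames = frames  # list[ViewFrame], length B
        self.imgs = imgs  # Tensor (B, 3, side, side), values in [0, 1]
        self.names = names  # list[str]
        self.src_levels = src_levels  # list[int]


class MagNet(nn.Module):
    def __init__(self, config: MagNetConfig, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng()
        self.config = config
        L, P = config.layers, config.patches
        self.branches: dict[str, Branch] = {}
        for l in range(1, L + 1):
            n_views = prod(P[: l - 1])
            for v in range(n_views):
                for p in range(1, P[l - 1] + 1):
                    if self._is_frozen(l, p):
                        continue
                    self.branches[f"l{l}v{v}p{p}"] = Branch(
                        channels=config.branch_channels, rng=rng
                    )
        self.backbone = make_backbone(config.backbone, config.backbone_channels, rng)
        self.gru = nn.GRU(self.backbone.feature_dim, config.gru_hidden, rng=rng)
        h1, h2 = config.head_sizes
        self.head = nn.Sequential(
            nn.Linear(config.gru_hidden, h1, rng=rng),
            nn.ReLU(),
            nn.Linear(h1, h2, rng=rng),
            nn.ReLU(),
            nn.Linear(h2, 1, rng=rng),
        )
        aux_ch = config.aux_channels or config.backbone_channels
        deep_aux = max(config.aux_layers)
        self.aux = {
            str(l): _AuxClassifier(
                aux_ch, rng,
                backbone=(
                    self.backbone
                    if config.share_aux_backbone and l == deep_aux == config.layers
                    else None
                ),
            )
            for l in config.aux_layers
        }

    def _is_frozen(self, layer: int, slot: int) -> bool:
        return self.config.frozen_patch and layer == 2 and slot == 1

    # -- plumbing ------------------------------------------------------------

    def _read_batch(self, pyramids, frames, side) -> np.ndarray:
        """Fresh, grey-filtered reads as a (B, 3, side, side) [0,1] array."""
        imgs = [
            grey_filter(read_region(pyr, fr, side), self.config.grey_tau)
            for pyr, fr in zip(pyramids, frames)
        ]
        return np.stack(imgs).astype(np.float32).transpose(0, 3, 1, 2) / 255.0

    def _grey_mask_t(self, img: Tensor) -> Tensor:
        """Re-apply the grey filter to sampled (already-unit-scale) patches."""
        d = img.data * 255.0
        spread = d.max(axis=1) - d.min(axis=1)
        keep = (spread >= self.config.grey_tau)[:, None, :, :]
        return img * Tensor(keep.astype(img.data.dtype))

    def _src_level(self, pyramid, frame) -> int:
        hc = min(max(frame.hc, 1.0), float(pyramid.h0))
        wc = min(max(frame.wc, 1.0), float(pyramid.w0))
        return select_level(pyramid.h0, pyramid.w0, hc, wc, pyramid.mmax)

    def _layer_step(self, layer, views, pyramids, rng, training,
                    theta_override=None):
        """Apply magnifying layer ``layer`` to every incoming view slot.

        Returns (child view batches in depth-first order, trace info), where
        trace info is a list of (parent_names, slot, thetas per slide,
        src levels, frames, resolution) tuples aligned with the children.
        """
        cfg = self.config
        B = len(pyramids)
        last = layer == cfg.layers
        out_side = cfg.final_side if last else cfg.in_side
        src_side = cfg.final_side if last else cfg.hi_side
        noise = 0.0
        if training:
            noise = cfg.noise_sd if cfg.noise_sd is not None else 1.0 / out_side
        children = []
        for v, view in enumerate(views):
            src = np.stack(
                [
                    grey_filter(
                        read_region(pyr, fr, src_side), cfg.grey_tau
                    )
                    for pyr, fr in zip(pyramids, view.frames)
                ]
            ).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
            src_levels = [
                self._src_level(pyr, fr)
                for pyr, fr in zip(pyramids, view.frames)
            ]
            for p in range(1, cfg.patches[layer - 1] + 1):
                override = None
                if theta_override is not None:
                    override = theta_override(layer, v, p)
                if override is not None:
                    s = Tensor(np.full(B, override.s, dtype=np.float32))
                    tx = Tensor(np.full(B, override.tx, dtype=np.float32))
                    ty = Tensor(np.full(B, override.ty, dtype=np.float32))
                elif self._is_frozen(layer, p):
                    s = Tensor(np.ones(B, dtype=np.float32))
                    tx = Tensor(np.zeros(B, dtype=np.float32))
                    ty = Tensor(np.zeros(B, dtype=np.float32))
                else:
                    amap = self.branches[f"l{layer}v{v}p{p}"](view.imgs)
                    s_raw, tx_raw, ty_raw = infer_affine_params_t(amap)
                    s, tx, ty = constrain_params_t(s_raw, tx_raw, ty_raw)
                thetas = [
                    AffineParams(
                        float(s.data[b]), float(tx.data[b]), float(ty.data[b])
                    )
                    for b in range(B)
                ]
                frames = [
                    compose_frames(fr, th)
                    for fr, th in zip(view.frames, thetas)
                ]
                img = affine_sample(
                    src, s, tx, ty, out_side,
                    k_aux=cfg.k_aux, noise_sd=noise, rng=rng,
                )
                img = self._grey_mask_t(img)
                names = [name + str(p) for name in view.names]
                children.append(
                    _ViewBatch(frames, img, names, src_levels)
                )
        return children

    # -- the network proper --------------------------------------------------

    def forward_batch(self, pyramids: list, rng: np.random.Generator | None = None,
                      theta_override=None, build_trace: bool = True) -> ForwardResult:
        cfg = self.config
        B = len(pyramids)
        root_frames = [root_frame(p) for p in pyramids]
        root_imgs = Tensor(self._read_batch(pyramids, root_frames, cfg.in_side))
        views = [
            _ViewBatch(
                root_frames,
                root_imgs,
                ["I1"] * B,
                [self._src_level(p, f) for p, f in zip(pyramids, root_frames)],
            )
        ]
        traces = None
        if build_trace:
            traces = [PatchTrace() for _ in range(B)]
            for b in range(B):
                traces[b].entries.append(
                    TraceEntry(
                        name="I1", parent=None, layer=0, slot=None, theta=None,
                        level=views[0].src_levels[b], frame=root_frames[b],
                        resolution=cfg.in_side,
                    )
                )

        aux_patches: dict[int, list] = {l: [] for l in cfg.aux_layers}
        finals: list[Tensor] = []
        for layer in range(1, cfg.layers + 1):
            parents = views
            views = self._layer_step(
                layer, parents, pyramids, rng, self.training, theta_override
            )
            if build_trace:
                for child in views:
                    for b in range(B):
                        name = child.names[b]
                        slot = int(name[-1])
                        traces[b].entries.append(
                            TraceEntry(
                                name=name,
                                parent=name[:-1],
                                layer=layer,
                                slot=slot,
                                theta=None,  # filled below
                                level=child.src_levels[b],
                                frame=child.frames[b],
                                resolution=(
                                    cfg.final_side
                                    if layer == cfg.layers
                                    else cfg.in_side
                                ),
                            )
                        )
            if layer in aux_patches:
                aux_patches[layer] = [child.imgs for child in views]
            if layer == cfg.layers:
                finals = [child.imgs for child in views]

        # reconstruct per-entry thetas from composed frames (cheap, exact)
        if build_trace:
            for trace in traces:
                lookup = trace.by_name()
                for e in trace.entries:
                    if e.parent is None:
                        continue
                    parent = lookup[e.parent]
                    s = e.frame.half_w / parent.frame.half_w
                    tx = (e.frame.center_x - parent.frame.center_x) / parent.frame.half_w
                    ty = (e.frame.center_y - parent.frame.center_y) / parent.frame.half_h
                    e.theta = AffineParams(float(s), float(tx), float(ty))

        y_hat = self.classification_head_t(finals)
        aux = {
            l: self.aux[str(l)](patches)
            for l, patches in aux_patches.items()
            if patches
        }
        return ForwardResult(y_hat=y_hat, aux=aux, traces=traces)

    def forward(self, pyramid: PyramidImage, rng=None, theta_override=None) -> ForwardResult:
        """Single-slide forward pass; probabilities come back as floats."""
        res = self.forward_batch(
            [pyramid], rng=rng, theta_override=theta_override
        )
        return ForwardResult(
            y_hat=float(res.y_hat.data[0]),
            aux={l: float(t.data[0]) for l, t in res.aux.items()},
            traces=res.traces,
        )

    def classification_head_t(self, patch_tensors: list) -> Tensor:
        """Backbone -> GRU -> FC head over the ordered final patches.

        With a shared auxiliary backbone the per-patch features are detached
        before the GRU: the backbone is then supervised only by the (shallow,
        fast-converging) auxiliary objective, standing in for the pretrained
        feature extractor of the reference configuration, while the
        recurrent head learns on top of those features.
        """
        if not patch_tensors:
            raise ContractError("classification head received no patches")
        feats = [self.backbone(p) for p in patch_tensors]
        if self.config.share_aux_backbone:
            feats = [f.detach() for f in feats]
        hidden = self.gru(feats)
        return self.head(hidden).sigmoid().reshape(-1)

    def classification_head(self, patches: list) -> float:
        """Numpy convenience wrapper: ordered 224 x 224 x 3 patches -> y_hat."""
        if not patches:
            raise ContractError("classification head received no patches")
        tensors = [
            Tensor(
                np.asarray(p, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0
            )
            for p in patches
        ]
        was_training = self.training
        self.eval()
        out = float(self.classification_head_t(tensors).data[0])
        self.train(was_training)
        return out

    def magnifying_layer(self, views: list, pyramid: PyramidImage,
                         layer_index: int, rng=None, theta_override=None):
        """Apply one magnifying layer to a single slide.

        ``views`` is a list of ``(frame, image)`` pairs where ``image`` is
        the 56 x 56 x 3 view (0-255).  Returns ``(children, entries)`` with
        children as ``(frame, image)`` pairs at the layer's output
        resolution and one :class:`TraceEntry` per child.
        """
        cfg = self.config
        batches = []
        for frame, img in views:
            t = Tensor(
                np.asarray(img, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0
            )
            batches.append(
                _ViewBatch([frame], t, ["I?"], [self._src_level(pyramid, frame)])
            )
        was_training = self.training
        self.eval()
        children = []
        entries = []
        for v, view in enumerate(batches):
            step = self._layer_step(
                layer_index, [view], [pyramid], rng, False, theta_override
            )
            for child in step:
                img_np = (
                    child.imgs.data[0].transpose(1, 2, 0) * 255.0
                ).clip(0, 255)
                children.append((child.frames[0], img_np))
                entries.append(
                    TraceEntry(
                        name=child.names[0],
                        parent="I?",
                        layer=layer_index,
                        slot=int(child.names[0][-1]),
                        theta=None,
                        level=child.src_levels[0],
                        frame=child.frames[0],
                        resolution=(
                            cfg.final_side
                            if layer_index == cfg.layers
                            else cfg.in_side
                        ),
                    )
                )
        self.train(was_training)
        return children, entries


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: MagNet, extra: dict | None = None):
    """Single-file archive of named parameter arrays plus the config."""
    cfg = asdict(model.config)
    payload = {
        "__config__": np.frombuffer(
            json.dumps({"config": cfg, "extra": extra or {}}).encode(), dtype=np.uint8
        )
    }
    payload.update(model.state_dict())
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path, rng=None) -> tuple[MagNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg_dict = meta["config"]
    for key in ("patches", "backbone_channels", "head_sizes"):
        cfg_dict[key] = tuple(cfg_dict[key])
    if cfg_dict.get("aux_channels"):
        cfg_dict["aux_channels"] = tuple(cfg_dict["aux_channels"])
    config = MagNetConfig(**cfg_dict)
    model = MagNet(config, rng=rng or np.random.default_rng(0))
    model.load_state_dict(state)
    return model, meta["extra"]
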