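"""Hierarchical image encoder with residual adapters over a frozen backbone.

The encoder mirrors the hierarchical vision-transformer layout used by
large promptable segmentation models: four sequential stages of
progressively wider embeddings and coarser spatial resolution, each stage
a sequence of blocks.  Task adaptation is done with lightweight residual
adapters inserted *before* every block while the backbone stays frozen:

    feat_adapter = W_up . gelu(W_down . feat)      (bottleneck projection)
    feat_final   = feat + feat_adapter             (residual; identity at
                                                    zero up-projection)
    feat_next    = BLK(feat_final)                 (frozen block)

``W_down`` is unshared (one per block); ``W_up`` is shared across the
blocks of a sharing group.  With the default ``per_stage`` sharing each
stage owns one shared up-projection.  A ``global`` mode shares a single
bottleneck-space core across *all* stages and keeps per-stage output
projections, because a literally global up-projection cannot satisfy the
residual dimension constraint when stage widths differ (144 vs 1152 in
the large preset).

The backbone is pluggable through :class:`Backbone`.  The in-package
:class:`ToyBackbone` is a small strided patch-embedding pyramid with
frozen random residual-MLP blocks: it reproduces the stage layout, block
count, and freezing semantics of the large pretrained encoder at a size
that trains in seconds on one CPU.  A real pretrained encoder can be
plugged in by implementing the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .particles import Micrograph

__all__ = [
    "StageSpec",
    "FeatureMap",
    "AdapterParams",
    "AdapterBank",
    "Backbone",
    "ToyBackbone",
    "make_stage_specs",
    "init_adapters",
    "adapter_apply",
    "encode",
    "count_trainable_params",
    "gelu",
]

#: stage layout of the large hierarchical encoder preset
LARGE_DIMS = (144, 288, 576, 1152)
LARGE_DEPTHS = (2, 6, 36, 4)
STAGE_SCALES = (4, 8, 16, 32)
LARGE_INPUT_SIZE = 1024


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact GELU: ``x * Phi(x)`` with Phi the standard normal CDF."""
    return x * ndtr(x)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """Derivative of exact GELU: ``Phi(x) + x * phi(x)``."""
    return ndtr(x) + x * np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class StageSpec:
    """Layout of one encoder stage."""

    index: int  # 1-based stage index
    embed_dim: int  # channels per token
    depth: int  # number of blocks = number of adapters
    spatial_scale: int  # downsampling factor relative to the input

    def __post_init__(self) -> None:
        if self.embed_dim <= 0 or self.depth <= 0:
            raise ValueError("embed_dim and depth must be strictly positive")


@dataclass
class FeatureMap:
    """Dense token grid: ``values`` has shape (batch, height, width, channels)."""

    values: np.ndarray
    stage_index: int
    block_index: int


def make_stage_specs(
    preset: str = "paper_large", toy_scale: int = 8
) -> list[StageSpec]:
    """Stage layouts: the published large preset, or a scaled-down toy.

    ``paper_large`` is the printed layout: dims (144, 288, 576, 1152) with
    depths (2, 6, 36, 4).  ``toy`` keeps the depths and divides every dim
    by ``toy_scale`` (which must divide them all).
    """
    if preset == "paper_large":
        dims = LARGE_DIMS
    elif preset == "toy":
        if any(d % toy_scale for d in LARGE_DIMS):
            raise ValueError(
                f"toy_scale={toy_scale} does not divide all stage dims {LARGE_DIMS}"
            )
        dims = tuple(d // toy_scale for d in LARGE_DIMS)
    else:
        raise ValueError(f"unknown preset {preset!r} (use 'paper_large' or 'toy')")
    return [
        StageSpec(i + 1, dims[i], LARGE_DEPTHS[i], STAGE_SCALES[i]) for i in range(4)
    ]


# ---------------------------------------------------------------------------
# adapters


@dataclass
class AdapterParams:
    """Parameter views for one block's adapter.

    ``up_layers`` holds the linear maps applied after the activation, in
    order.  In ``per_stage`` sharing it is a single shared
    (bottleneck -> embed_dim) layer; in ``global`` sharing it is the
    globally shared bottleneck core followed by the stage output
    projection.  The arrays are *references*: mutating a shared layer
    changes every adapter in its sharing group.
    """

    W_down: np.ndarray
    b_down: np.ndarray
    up_layers: tuple[tuple[np.ndarray, np.ndarray], ...]
    name_down: str
    names_up: tuple[str, ...]


class AdapterBank:
    """All adapter parameters for an encoder, organised per stage/block."""

    def __init__(
        self,
        specs: list[StageSpec],
        sharing: str,
        blocks: list[list[AdapterParams]],
        params: dict[str, np.ndarray],
    ):
        self.specs = specs
        self.sharing = sharing
        self.blocks = blocks  # blocks[stage][block] -> AdapterParams
        self._params = params  # name -> array (each unique array once)

    def adapter(self, stage: int, block: int) -> AdapterParams:
        """0-based stage and block indices."""
        return self.blocks[stage][block]

    def named_parameters(self):
        for name, arr in self._params.items():
            yield name, arr, True

    @property
    def n_unshared_layers(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def n_shared_layers(self) -> int:
        ups = {id(layer[0]) for b in self.blocks for a in b for layer in a.up_layers}
        return len(ups)


def init_adapters(
    specs: list[StageSpec],
    bottleneck_ratio: float = 0.25,
    sharing: str = "per_stage",
    seed: int = 0,
    bottleneck_dim: int | None = None,
) -> AdapterBank:
    """Create adapter parameters for every block of every stage.

    Down-projections are unshared (one per block) and initialized with
    small Gaussian weights (sd 0.02); shared up-projections start at zero
    so the whole encoder begins at the frozen backbone's function exactly
    (residual identity).

    Parameters
    ----------
    bottleneck_ratio
        Bottleneck width as a fraction of the stage embedding dim
        (ignored when ``bottleneck_dim`` is given).
    sharing
        ``per_stage`` (one shared up-projection per stage) or ``global``
        (one shared bottleneck core across all stages plus per-stage
        output projections; requires a common bottleneck dim).
    """
    if not 0.0 < bottleneck_ratio <= 1.0:
        raise ValueError(f"bottleneck_ratio must lie in (0, 1], got {bottleneck_ratio}")
    if sharing not in ("per_stage", "global"):
        raise ValueError(f"unknown sharing mode {sharing!r}")
    rng = np.random.default_rng(seed)

    if bottleneck_dim is not None:
        bdims = [int(bottleneck_dim)] * len(specs)
    else:
        bdims = [max(1, round(s.embed_dim * bottleneck_ratio)) for s in specs]
    if sharing == "global" and len(set(bdims)) > 1:
        raise ValueError(
            "global sharing needs one common bottleneck dim, but per-stage "
            f"bottleneck dims {bdims} differ; pass bottleneck_dim explicitly"
        )

    params: dict[str, np.ndarray] = {}
    blocks: list[list[AdapterParams]] = []

    core = None
    if sharing == "global":
        b = bdims[0]
        core = (np.zeros((b, b)), np.zeros(b))
        params["adapter.core.W"] = core[0]
        params["adapter.core.b"] = core[1]

    for si, (spec, b) in enumerate(zip(specs, bdims)):
        d = spec.embed_dim
        if sharing == "per_stage":
            up = (np.zeros((b, d)), np.zeros(d))
            params[f"adapter.s{si + 1}.up.W"] = up[0]
            params[f"adapter.s{si + 1}.up.b"] = up[1]
            up_layers = ((up[0], up[1]),)
            names_up = (f"adapter.s{si + 1}.up",)
        else:
            out = (rng.normal(0.0, 0.02, size=(b, d)), np.zeros(d))
            params[f"adapter.s{si + 1}.out.W"] = out[0]
            params[f"adapter.s{si + 1}.out.b"] = out[1]
            up_layers = ((core[0], core[1]), (out[0], out[1]))
            names_up = ("adapter.core", f"adapter.s{si + 1}.out")

        stage_blocks = []
        for bj in range(spec.depth):
            W_down = rng.normal(0.0, 0.02, size=(d, b))
            b_down = np.zeros(b)
            name = f"adapter.s{si + 1}.b{bj + 1}.down"
            params[f"{name}.W"] = W_down
            params[f"{name}.b"] = b_down
            stage_blocks.append(
                AdapterParams(W_down, b_down, up_layers, name, names_up)
            )
        blocks.append(stage_blocks)

    return AdapterBank(specs, sharing, blocks, params)


def _adapter_forward(adapter: AdapterParams, x: np.ndarray, need_cache: bool):
    u = x @ adapter.W_down + adapter.b_down
    h = gelu(u)
    ins = [h] if need_cache else None
    for W, b in adapter.up_layers:
        h = h @ W + b
        if need_cache:
            ins.append(h)
    y = x + h
    cache = {"x": x, "u": u, "ins": ins} if need_cache else None
    return y, cache


def _adapter_backward(
    adapter: AdapterParams, cache: dict, g: np.ndarray, grads: dict[str, np.ndarray]
) -> np.ndarray:
    """Accumulate parameter grads into ``grads``; return grad w.r.t. input."""

    def acc(name, val):
        if name in grads:
            grads[name] += val
        else:
            grads[name] = val

    dh = g
    for k in reversed(range(len(adapter.up_layers))):
        W, _b = adapter.up_layers[k]
        inp = cache["ins"][k]
        cin, cout = W.shape
        acc(
            adapter.names_up[k] + ".W",
            inp.reshape(-1, cin).T @ dh.reshape(-1, cout),
        )
        acc(adapter.names_up[k] + ".b", dh.reshape(-1, cout).sum(axis=0))
        dh = dh @ W.T
    du = dh * gelu_grad(cache["u"])
    d = adapter.W_down.shape[0]
    b = adapter.W_down.shape[1]
    acc(
        adapter.name_down + ".W",
        cache["x"].reshape(-1, d).T @ du.reshape(-1, b),
    )
    acc(adapter.name_down + ".b", du.reshape(-1, b).sum(axis=0))
    return g + du @ adapter.W_down.T


def adapter_apply(adapter: AdapterParams, feat: FeatureMap) -> FeatureMap:
    """Apply one residual adapter: ``feat + W_up . gelu(W_down . feat)``."""
    vals = feat.values
    if vals.shape[-1] != adapter.W_down.shape[0]:
        raise ValueError(
            f"feature channels {vals.shape[-1]} do not match adapter input dim "
            f"{adapter.W_down.shape[0]}"
        )
    y, _ = _adapter_forward(adapter, vals, need_cache=False)
    return FeatureMap(y, feat.stage_index, feat.block_index)


# ---------------------------------------------------------------------------
# backbone


def _patchify(x: np.ndarray, p: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H/p, W/p, p*p*C): non-overlapping patch flatten."""
    n, h, w, c = x.shape
    x = x.reshape(n, h // p, p, w // p, p, c)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // p, w // p, p * p * c)


def _unpatchify(x: np.ndarray, p: int, c: int) -> np.ndarray:
    n, hp, wp, _ = x.shape
    x = x.reshape(n, hp, wp, p, p, c).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n, hp * p, wp * p, c)


class Backbone:
    """Contract for a pluggable frozen hierarchical backbone.

    Implementations provide ``stage_specs``, a ``frozen`` flag, per-stage
    patch embeddings and per-block transforms, plus the corresponding
    vector-Jacobian products so adapters upstream of a block still receive
    gradients while the backbone's own parameters stay untouched.
    """

    stage_specs: list[StageSpec]
    frozen: bool = True

    def embed_forward(self, stage: int, x: np.ndarray, need_cache: bool):
        raise NotImplementedError

    def embed_backward(self, stage: int, cache, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def block_forward(self, stage: int, block: int, x: np.ndarray, need_cache: bool):
        raise NotImplementedError

    def block_backward(self, stage: int, block: int, cache, g: np.ndarray):
        raise NotImplementedError

    def named_parameters(self):
        raise NotImplementedError


class ToyBackbone(Backbone):
    """Strided patch-embedding pyramid with frozen residual-MLP blocks.

    Stage ``i`` downsamples by ``spatial_scale[i] / spatial_scale[i-1]``
    via non-overlapping patch flattening followed by a linear projection
    to the stage width (a strided convolution), then applies ``depth``
    frozen blocks ``x -> x + gelu(x W + b)``.
    """

    def __init__(self, specs: list[StageSpec], in_channels: int = 1, seed: int = 0):
        self.stage_specs = list(specs)
        self.in_channels = in_channels
        self.frozen = True
        rng = np.random.default_rng(seed)
        self._embed = []
        self._blocks = []
        prev_dim = in_channels
        prev_scale = 1
        for s in specs:
            p = s.spatial_scale // prev_scale
            if p * prev_scale != s.spatial_scale:
                raise ValueError("stage scales must be nested multiples")
            in_dim = p * p * prev_dim
            We = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, s.embed_dim))
            be = np.zeros(s.embed_dim)
            self._embed.append((p, We, be))
            stage_blocks = []
            for _ in range(s.depth):
                Wb = rng.normal(
                    0.0, 0.5 / np.sqrt(s.embed_dim), size=(s.embed_dim, s.embed_dim)
                )
                bb = np.zeros(s.embed_dim)
                stage_blocks.append((Wb, bb))
            self._blocks.append(stage_blocks)
            prev_dim = s.embed_dim
            prev_scale = s.spatial_scale

    def embed_forward(self, stage: int, x: np.ndarray, need_cache: bool):
        p, We, be = self._embed[stage]
        patches = _patchify(x, p)
        y = patches @ We + be
        cache = {"in_channels": x.shape[-1]} if need_cache else None
        return y, cache

    def embed_backward(self, stage: int, cache, g: np.ndarray) -> np.ndarray:
        p, We, _ = self._embed[stage]
        return _unpatchify(g @ We.T, p, cache["in_channels"])

    def block_forward(self, stage: int, block: int, x: np.ndarray, need_cache: bool):
        Wb, bb = self._blocks[stage][block]
        u = x @ Wb + bb
        y = x + gelu(u)
        cache = {"u": u} if need_cache else None
        return y, cache

    def block_backward(self, stage: int, block: int, cache, g: np.ndarray):
        Wb, _ = self._blocks[stage][block]
        return g + (g * gelu_grad(cache["u"])) @ Wb.T

    def named_parameters(self):
        trainable = not self.frozen
        for si, (p, We, be) in enumerate(self._embed):
            yield f"backbone.s{si + 1}.embed.W", We, trainable
            yield f"backbone.s{si + 1}.embed.b", be, trainable
        for si, stage_blocks in enumerate(self._blocks):
            for bj, (Wb, bb) in enumerate(stage_blocks):
                yield f"backbone.s{si + 1}.b{bj + 1}.W", Wb, trainable
                yield f"backbone.s{si + 1}.b{bj + 1}.b", bb, trainable

    def state_copy(self) -> dict[str, np.ndarray]:
        """Deep copy of all backbone arrays (for freeze-conservation checks)."""
        return {name: arr.copy() for name, arr, _ in self.named_parameters()}


# ---------------------------------------------------------------------------
# full encoder forward/backward


def _check_compat(backbone: Backbone, adapters: AdapterBank | None) -> None:
    if adapters is None:
        return
    bs = [(s.embed_dim, s.depth) for s in backbone.stage_specs]
    as_ = [(s.embed_dim, s.depth) for s in adapters.specs]
    if bs != as_:
        raise ValueError(
            f"backbone stages {bs} do not match adapter stages {as_}"
        )


def _encoder_forward(
    x: np.ndarray,
    backbone: Backbone,
    adapters: AdapterBank | None,
    need_cache: bool = False,
):
    """Run all stages; return per-stage final features (+ cache for vjp).

    ``adapters=None`` runs the bare backbone (used by the residual-identity
    tests and by :func:`encode` when no adapters are supplied).
    """
    _check_compat(backbone, adapters)
    finals = []
    cache = {"stages": []} if need_cache else None
    for si, spec in enumerate(backbone.stage_specs):
        x, ec = backbone.embed_forward(si, x, need_cache)
        stage_cache = {"embed": ec, "blocks": []} if need_cache else None
        for bj in range(spec.depth):
            if adapters is not None:
                a = adapters.adapter(si, bj)
                x, ac = _adapter_forward(a, x, need_cache)
            else:
                ac = None
            x, bc = backbone.block_forward(si, bj, x, need_cache)
            if need_cache:
                stage_cache["blocks"].append({"adapter": ac, "block": bc})
        finals.append(x)
        if need_cache:
            cache["stages"].append(stage_cache)
    return finals, cache


def _encoder_backward(
    cache,
    stage_grads: list[np.ndarray],
    backbone: Backbone,
    adapters: AdapterBank | None,
) -> dict[str, np.ndarray]:
    """Backpropagate grads w.r.t. each stage's final features.

    Returns parameter grads for the adapters only (the backbone is frozen;
    its parameters receive no gradient by construction).
    """
    grads: dict[str, np.ndarray] = {}
    g = None
    for si in reversed(range(len(backbone.stage_specs))):
        sc = cache["stages"][si]
        g = stage_grads[si] if g is None else g + stage_grads[si]
        for bj in reversed(range(backbone.stage_specs[si].depth)):
            bc = sc["blocks"][bj]
            g = backbone.block_backward(si, bj, bc["block"], g)
            if adapters is not None:
                g = _adapter_backward(
                    adapters.adapter(si, bj), bc["adapter"], g, grads
                )
        g = backbone.embed_backward(si, sc["embed"], g)
    return grads


def _as_batch(image) -> np.ndarray:
    if isinstance(image, Micrograph):
        image = image.data
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, :, :, None]
    elif x.ndim == 3:
        x = x[..., None]
    elif x.ndim != 4:
        raise ValueError(f"expected 2-D image or batch, got shape {x.shape}")
    return x


def encode(
    image, backbone: Backbone, adapters: AdapterBank | None
) -> list[FeatureMap]:
    """Encode an image through all stages, adapters applied before blocks.

    ``image`` must already be at the model input size (a multiple of the
    deepest stage's spatial scale).  Returns the final feature map of each
    stage at its spatial scale.
    """
    x = _as_batch(image)
    top = backbone.stage_specs[-1].spatial_scale
    if x.shape[1] % top or x.shape[2] % top:
        raise ValueError(
            f"input size {x.shape[1]}x{x.shape[2]} must be divisible by the "
            f"deepest stage scale {top}"
        )
    finals, _ = _encoder_forward(x, backbone, adapters, need_cache=False)
    return [
        FeatureMap(f, spec.index, spec.depth)
        for f, spec in zip(finals, backbone.stage_specs)
    ]


def count_trainable_params(model) -> int:
    """Number of scalar parameters flagged trainable in ``model``.

    ``model`` is anything exposing ``named_parameters()`` yielding
    ``(name, array, trainable)`` triples (e.g. :class:`AdapterBank`,
    :class:`ToyBackbone`, or the assembled segmentation model).
    """
    return sum(arr.size for _name, arr, trainable in model.named_parameters() if trainable)
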