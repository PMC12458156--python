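"""Assembled few-shot segmentation model: backbone + adapters + decoder.

The decoder is a small upsampling head implementing the decoder
contract: each stage's final feature map is projected to a
single logit channel, upsampled (nearest-neighbor) to the model input
size, and summed together with a learnable skip connection from the
normalized input intensity.  The skip lets the head resolve particle
boundaries at full resolution while the stage projections contribute
multi-scale context; it keeps the trainable surface tiny, which is the
point of the adapter approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import (
    AdapterBank,
    Backbone,
    StageSpec,
    ToyBackbone,
    _as_batch,
    _encoder_backward,
    _encoder_forward,
    init_adapters,
    make_stage_specs,
)

__all__ = ["LogitMap", "DecoderHead", "SegModel", "build_toy_model"]


@dataclass
class LogitMap:
    """Per-pixel segmentation logits at model resolution.

    ``native_shape`` records the micrograph's original (height, width) so
    coordinates can be mapped back from model space.
    """

    values: np.ndarray  # (H, W) at model resolution
    native_shape: tuple[int, int] | None = None

    @property
    def input_size(self) -> int:
        return self.values.shape[0]


def _upsample_nearest(x: np.ndarray, f: int) -> np.ndarray:
    return np.repeat(np.repeat(x, f, axis=1), f, axis=2)


def _downsample_sum(g: np.ndarray, f: int) -> np.ndarray:
    n, h, w = g.shape
    return g.reshape(n, h // f, f, w // f, f).sum(axis=(2, 4))


class DecoderHead:
    """Per-stage linear logit projections + image skip, all trainable."""

    def __init__(self, specs: list[StageSpec], seed: int = 0):
        rng = np.random.default_rng(seed)
        self.specs = list(specs)
        self.w_stage = [
            rng.normal(0.0, 0.01, size=s.embed_dim) for s in specs
        ]
        self.w_img = np.array([rng.normal(0.0, 0.01)])
        self.b = np.zeros(1)
        self.trainable = True

    def named_parameters(self):
        for si, w in enumerate(self.w_stage):
            yield f"decoder.s{si + 1}.w", w, self.trainable
        yield "decoder.w_img", self.w_img, self.trainable
        yield "decoder.b", self.b, self.trainable

    def forward(self, x_img: np.ndarray, finals: list[np.ndarray], need_cache: bool):
        n, size = x_img.shape[0], x_img.shape[1]
        logits = np.full((n, size, size), self.b[0])
        logits += self.w_img[0] * x_img[..., 0]
        for w, f, spec in zip(self.w_stage, finals, self.specs):
            logits += _upsample_nearest(f @ w, spec.spatial_scale)
        cache = {"x_img": x_img, "finals": finals} if need_cache else None
        return logits, cache

    def backward(self, cache, g: np.ndarray):
        """Return (param grads, per-stage feature grads)."""
        grads: dict[str, np.ndarray] = {
            "decoder.b": np.array([g.sum()]),
            "decoder.w_img": np.array([(g * cache["x_img"][..., 0]).sum()]),
        }
        stage_grads = []
        for si, (w, f, spec) in enumerate(
            zip(self.w_stage, cache["finals"], self.specs)
        ):
            gi = _downsample_sum(g, spec.spatial_scale)
            grads[f"decoder.s{si + 1}.w"] = np.einsum("nhw,nhwc->c", gi, f)
            stage_grads.append(gi[..., None] * w)
        return grads, stage_grads


class SegModel:
    """Frozen backbone + trainable adapters + trainable decoder head."""

    def __init__(
        self,
        backbone: Backbone,
        adapters: AdapterBank,
        decoder: DecoderHead,
        input_size: int,
    ):
        self.backbone = backbone
        self.adapters = adapters
        self.decoder = decoder
        self.input_size = int(input_size)
        top = backbone.stage_specs[-1].spatial_scale
        if self.input_size % top:
            raise ValueError(
                f"input_size {input_size} must be divisible by the deepest "
                f"stage scale {top}"
            )

    def named_parameters(self):
        yield from self.backbone.named_parameters()
        yield from self.adapters.named_parameters()
        yield from self.decoder.named_parameters()

    def trainable_params(self) -> dict[str, np.ndarray]:
        return {n: a for n, a, t in self.named_parameters() if t}

    def forward(self, images, need_cache: bool = False):
        """Images (already normalized/resized) -> logits (N, S, S)."""
        x = _as_batch(images)
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"model expects {self.input_size}x{self.input_size} input, "
                f"got {x.shape[1]}x{x.shape[2]}"
            )
        finals, enc_cache = _encoder_forward(
            x, self.backbone, self.adapters, need_cache
        )
        logits, dec_cache = self.decoder.forward(x, finals, need_cache)
        cache = {"enc": enc_cache, "dec": dec_cache} if need_cache else None
        return logits, cache

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every *trainable* parameter.

        The frozen backbone receives no parameter gradients (its blocks
        only pass gradients through to upstream adapters).
        """
        dec_grads, stage_grads = self.decoder.backward(cache["dec"], dlogits)
        enc_grads = _encoder_backward(
            cache["enc"], stage_grads, self.backbone, self.adapters
        )
        return {**dec_grads, **enc_grads}

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Save all parameters (frozen backbone included) to an .npz file."""
        arrays = {n: a for n, a, _t in self.named_parameters()}
        meta = dict(
            input_size=self.input_size,
            dims=[s.embed_dim for s in self.backbone.stage_specs],
            depths=[s.depth for s in self.backbone.stage_specs],
            sharing=self.adapters.sharing,
        )
        np.savez(path, __meta__=np.array([repr(meta)]), **arrays)

    def load_params(self, path) -> None:
        data = np.load(path, allow_pickle=False)
        for name, arr, _t in self.named_parameters():
            arr[...] = data[name]


def build_toy_model(
    toy_scale: int = 8,
    input_size: int = 64,
    bottleneck_ratio: float = 0.25,
    sharing: str = "per_stage",
    seed: int = 0,
) -> SegModel:
    """Assemble the desk-scale model: toy backbone, adapters, decoder head."""
    specs = make_stage_specs("toy", toy_scale=toy_scale)
    backbone = ToyBackbone(specs, seed=seed)
    adapters = init_adapters(
        specs, bottleneck_ratio=bottleneck_ratio, sharing=sharing, seed=seed + 1
    )
    decoder = DecoderHead(specs, seed=seed + 2)
    return SegModel(backbone, adapters, decoder, input_size)
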