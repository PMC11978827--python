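"""Image-side encoder: a small self-contained conv backbone plus projection
heads producing one global feature and one local feature per brain ROI.

The backbone (``tiny_conv``) maps an H x W x 3 image through four conv
stages — a non-overlapping patchify to a 28 x 28 grid, two stride-2 3x3
convs, and a final stride-1 3x3 conv — down to a 7 x 7 feature grid.  The global feature is a
fully connected projection of the grid mean; each local head is a fully
connected projection of the flattened grid, so heads can specialize to
different image regions.  ``external`` accepts any callable producing a
(batch, gh, gw, c) grid for users who bring their own backbone.

Weight archives are single files: a JSON manifest line (architecture string,
tensor names/shapes, SHA-256 of the payload) followed by the concatenated raw
float64 tensor bytes.  Loading verifies the checksum, so truncation or
bit-flips are detected rather than silently corrupting weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .nn import Conv2d, Linear, Module

__all__ = [
    "BackboneSpec",
    "VisualFeature",
    "VisionEncoder",
    "encode_image",
    "export_backbone",
    "load_backbone",
    "grid_receptive_field",
]

IMG_SIZE_DEFAULT = 224
_STAGE_CHANNELS = (8, 16, 16, 32)
_GRID_SIZE = 7


@dataclass
class BackboneSpec:
    """Backbone selection: self-contained ``tiny_conv`` or a user callable."""

    name: str = "tiny_conv"
    d: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("tiny_conv", "external"):
            raise ValueError(f"unknown backbone {self.name!r}")


@dataclass
class VisualFeature:
    """Global image feature plus per-ROI local features in the shared space."""

    global_feat: np.ndarray   # (d,) or (batch, d)
    local: np.ndarray         # (N_roi, d) or (batch, N_roi, d)


class VisionEncoder(Module):
    """tiny_conv backbone with a global head and one local head per ROI."""

    def __init__(self, spec: BackboneSpec, n_roi: int,
                 img_size: int = IMG_SIZE_DEFAULT,
                 external_backbone=None, external_channels: int | None = None):
        self.spec = spec
        self.n_roi = n_roi
        self.img_size = img_size
        rng = np.random.default_rng(spec.seed)
        if spec.name == "tiny_conv":
            if img_size % 28:
                raise ValueError(
                    f"tiny_conv requires img_size divisible by 28, got {img_size}")
            patch = img_size // 28
            c = _STAGE_CHANNELS
            self.stages = [
                Conv2d(3, c[0], kernel=patch, stride=patch, pad=0, rng=rng),
                Conv2d(c[0], c[1], kernel=3, stride=2, pad=1, rng=rng),
                Conv2d(c[1], c[2], kernel=3, stride=2, pad=1, rng=rng),
                Conv2d(c[2], c[3], kernel=3, stride=1, pad=1, rng=rng),
            ]
            grid_c = c[-1]
            self.external = None
        else:
            if external_backbone is None:
                raise ValueError("external backbone requires a callable")
            self.stages = []
            self.external = external_backbone
            grid_c = external_channels or spec.d
        self.grid_channels = grid_c
        self.global_head = Linear(grid_c, spec.d, rng)
        self.local_heads = [Linear(_GRID_SIZE * _GRID_SIZE * grid_c, spec.d, rng)
                            for _ in range(n_roi)]

    # -- forward -------------------------------------------------------------
    def grid_features(self, images: Tensor) -> Tensor:
        """(batch, H, W, 3) -> (batch, gh, gw, c) pre-projection feature grid."""
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(
                f"images must be (batch, H, W, 3), got {images.shape}")
        if images.shape[1] != self.img_size or images.shape[2] != self.img_size:
            raise ValueError(
                f"expected {self.img_size}x{self.img_size} images, "
                f"got {images.shape[1]}x{images.shape[2]}")
        if self.external is not None:
            return self.external(images)
        x = images
        for stage in self.stages:
            x = stage(x).relu()
        return x

    def __call__(self, images: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (global (b, d), local (b, N_roi, d))."""
        grid = self.grid_features(images)
        b, gh, gw, c = grid.shape
        global_feat = self.global_head(grid.reshape(b, gh * gw, c).mean(axis=1))
        flat = grid.reshape(b, gh * gw * c)
        local = stack([head(flat) for head in self.local_heads], axis=1)
        return global_feat, local


def encode_image(images: np.ndarray, encoder: VisionEncoder) -> VisualFeature:
    """Encode one image (H, W, 3) or a batch (B, H, W, 3) in [0, 1]."""
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 3
    if single:
        images = images[None]
    if images.min() < -1e-9 or images.max() > 1.0 + 1e-9:
        raise ValueError("image values must lie in [0, 1]")
    g, l = encoder(Tensor(images))
    if single:
        return VisualFeature(global_feat=g.data[0], local=l.data[0])
    return VisualFeature(global_feat=g.data, local=l.data)


def grid_receptive_field(encoder: VisionEncoder, row: int, col: int
                         ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Half-open pixel ranges ((r0, r1), (c0, c1)) feeding one final grid cell.

    Computed by interval arithmetic through the conv stages, clipped to the
    image; only defined for the tiny_conv backbone.
    """
    if encoder.external is not None:
        raise ValueError("receptive fields are only tracked for tiny_conv")
    r0, r1 = row, row + 1
    c0, c1 = col, col + 1
    for stage in reversed(encoder.stages):
        k, s, p = stage.kernel, stage.stride, stage.pad
        r0, r1 = r0 * s - p, (r1 - 1) * s - p + k
        c0, c1 = c0 * s - p, (c1 - 1) * s - p + k
    size = encoder.img_size
    return ((max(r0, 0), min(r1, size)), (max(c0, 0), min(c1, size)))


# -- weight archive ----------------------------------------------------------

_MAGIC = "neurofusion-weights-v1"


def _architecture_string(encoder: VisionEncoder) -> str:
    return (f"{encoder.spec.name}(d={encoder.spec.d}, n_roi={encoder.n_roi}, "
            f"img_size={encoder.img_size}, channels={list(_STAGE_CHANNELS)}, "
            f"grid={_GRID_SIZE}x{_GRID_SIZE})")


def export_backbone(encoder: VisionEncoder, path) -> str:
    """Serialize architecture + weights to ``path``; returns the arch string.

    Round trip through :func:`load_backbone` is bit-exact.
    """
    names, payload = [], []
    for name, p in encoder.named_parameters():
        arr = np.ascontiguousarray(p.data, dtype=np.float64)
        names.append({"name": name, "shape": list(arr.shape)})
        payload.append(arr.tobytes())
    blob = b"".join(payload)
    manifest = {
        "magic": _MAGIC,
        "architecture": _architecture_string(encoder),
        "spec": {"name": encoder.spec.name, "d": encoder.spec.d,
                 "seed": encoder.spec.seed},
        "n_roi": encoder.n_roi,
        "img_size": encoder.img_size,
        "tensors": names,
        "payload_sha256": hashlib.sha256(blob).hexdigest(),
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(manifest).encode() + b"\n")
        fh.write(blob)
    return manifest["architecture"]


class ArchiveError(RuntimeError):
    """Raised when a weight archive fails validation."""


def read_archive_manifest(path) -> dict:
    with open(path, "rb") as fh:
        header = fh.readline()
    manifest = json.loads(header)
    if manifest.get("magic") != _MAGIC:
        raise ArchiveError(f"{path} is not a weight archive")
    return manifest


def load_backbone(path) -> VisionEncoder:
    """Rebuild an encoder from an archive, verifying the payload checksum."""
    with open(path, "rb") as fh:
        header = fh.readline()
        blob = fh.read()
    manifest = json.loads(header)
    if manifest.get("magic") != _MAGIC:
        raise ArchiveError(f"{path} is not a weight archive")
    digest = hashlib.sha256(blob).hexdigest()
    if digest != manifest["payload_sha256"]:
        raise ArchiveError(
            f"payload checksum mismatch in {path}: archive is corrupt "
            f"(expected {manifest['payload_sha256'][:12]}..., got {digest[:12]}...)")
    spec = BackboneSpec(**manifest["spec"])
    encoder = VisionEncoder(spec, n_roi=manifest["n_roi"],
                            img_size=manifest["img_size"])
    params = dict(encoder.named_parameters())
    offset = 0
    for entry in manifest["tensors"]:
        shape = tuple(entry["shape"])
        count = int(np.prod(shape)) if shape else 1
        arr = np.frombuffer(blob, dtype=np.float64, count=count,
                            offset=offset).reshape(shape)
        offset += count * 8
        params[entry["name"]].data = arr.copy()
    return encoder
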