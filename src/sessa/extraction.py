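"""Image-to-feature front end: a pluggable backbone turning cell images into
flattened bottleneck feature matrices.

The contract mirrors the last convolutional block of a VGG19-style network:
224x224x3 input, a (7, 7, 512) feature map, flattened row-major over
(height, width, channel) into 25088 non-negative columns.  Two backbones
are provided: a weight-free random-filter backbone (deterministic from a
fixed seed, used everywhere in tests, no downloads) and an adapter stub for
a real pretrained VGG19 that raises an actionable error when the optional
deep-learning dependency is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "BackboneSpec",
    "preprocess_image",
    "RandomFilterBackbone",
    "VGG19Backbone",
    "extract_bottleneck",
    "load_image_directory",
]


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_side: int = 224
    output_shape: tuple[int, int, int] = (7, 7, 512)
    requires_weights: bool = False

    @property
    def flattened_dim(self) -> int:
        h, w, c = self.output_shape
        return h * w * c


def preprocess_image(image) -> np.ndarray:
    """Resize to 224x224x3 with values in [0, 1].

    Grayscale inputs are replicated across the three channels; uint8 inputs
    are scaled by 1/255.  Backbone-specific normalization (channel means
    etc.) is left to the backbone adapter.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3 or img.shape[2] not in (1, 3):
        raise ValueError(f"expected HxW, HxWx1 or HxWx3 image, got shape {np.shape(image)}")
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    if img.shape[:2] != (224, 224):
        img = resize(img, (224, 224), anti_aliasing=True, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


class RandomFilterBackbone:
    """Weight-free bottleneck backbone built from fixed-seed random filters.

    Pipeline: 4x4 block-mean downsample to 56x56, a bank of random 3x3
    convolutions (3 -> ``n_mid`` channels) with ReLU, 8x8 block-mean pooling
    to 7x7, then a random 1x1 projection ``n_mid`` -> 512 with ReLU.  All
    filters are drawn once from a generator seeded at construction, so the
    mapping is a fixed deterministic function — adequate wherever the
    pipeline contract (shapes, non-negativity, determinism) matters rather
    than pretrained-feature quality.
    """

    def __init__(self, seed: int = 2024, n_mid: int = 32):
        rng = np.random.default_rng(seed)
        self.spec = BackboneSpec(name=f"random-filter-{seed}", requires_weights=False)
        self.n_mid = n_mid
        self.filters = rng.standard_normal((n_mid, 3, 3, 3)) / 3.0
        self.bias = rng.standard_normal(n_mid) * 0.1
        self.projection = rng.standard_normal((n_mid, 512)) / np.sqrt(n_mid)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = preprocess_image(image)
        # 224 -> 56 block mean
        small = img.reshape(56, 4, 56, 4, 3).mean(axis=(1, 3))
        mid = np.empty((56, 56, self.n_mid))
        for k in range(self.n_mid):
            acc = np.zeros((56, 56))
            for c in range(3):
                acc += ndimage.convolve(small[:, :, c], self.filters[k, :, :, c], mode="nearest")
            mid[:, :, k] = acc + self.bias[k]
        mid = np.maximum(mid, 0.0)
        pooled = mid.reshape(7, 8, 7, 8, self.n_mid).mean(axis=(1, 3))
        fmap = np.maximum(pooled @ self.projection, 0.0)  # 7x7x512
        return fmap


class VGG19Backbone:
    """Adapter for a real pretrained VGG19 bottleneck extractor.

    Requires an optional deep-learning dependency with pretrained weights;
    nothing is ever downloaded implicitly.
    """

    def __init__(self):
        self.spec = BackboneSpec(name="vgg19", requires_weights=True)
        raise ImportError(
            "pretrained VGG19 extraction needs the optional 'torch' (or "
            "'tensorflow') dependency with locally available weights; "
            "install one and provide weights, or use RandomFilterBackbone "
            "for a weight-free pipeline"
        )


def _column_names(shape: tuple[int, int, int]) -> list[str]:
    h, w, c = shape
    return [f"r{i}c{j}k{k}" for i in range(h) for j in range(w) for k in range(c)]


def extract_bottleneck(images, backbone=None, sample_ids=None) -> pd.DataFrame:
    """Run each image through the backbone and flatten the (7, 7, 512)
    feature map row-major over (row, col, channel) into 25088 named columns
    (``r{row}c{col}k{channel}``)."""
    if backbone is None:
        backbone = RandomFilterBackbone()
    spec: BackboneSpec = backbone.spec
    rows = []
    for img in images:
        fmap = backbone(img)
        if fmap.shape != spec.output_shape:
            raise ValueError(
                f"backbone {spec.name!r} returned shape {fmap.shape}, expected {spec.output_shape}"
            )
        rows.append(fmap.reshape(-1))
    X = np.vstack(rows) if rows else np.empty((0, spec.flattened_dim))
    if sample_ids is None:
        sample_ids = [f"img{i:03d}" for i in range(X.shape[0])]
    return pd.DataFrame(
        X,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=_column_names(spec.output_shape),
    )


def load_image_directory(root: str | Path) -> tuple[list[np.ndarray], pd.Series]:
    """Read PNG/JPEG/TIFF images from class-named subdirectories
    (``class_0``, ``class_1``) into arrays plus a label Series."""
    from skimage.io import imread

    root = Path(root)
    images, labels, ids = [], [], []
    for sub in sorted(root.glob("class_*")):
        label = int(sub.name.split("_", 1)[1])
        for path in sorted(sub.iterdir()):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
                continue
            try:
                images.append(imread(path))
            except Exception as exc:  # noqa: BLE001
                raise IOError(f"could not read image {path}") from exc
            labels.append(label)
            ids.append(path.stem)
    return images, pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="label")
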