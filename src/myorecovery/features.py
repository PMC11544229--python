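"""Cell-image feature extraction.

Each segmented cell yields a 64x64 RGB "cell image" centered on its
centroid; a feature extractor maps it to a D-dimensional instance vector
x fed to the recovery-phase classifier.  The extractor is a pluggable
contract: the study used a self-supervised vision transformer (ViT-B/8
student checkpoint with average-pooled patch tokens, D configurable,
default 1536 for that backend).  Pretrained weights are not shipped here;
``register_extractor`` wires any external model, and the built-in
``"handcrafted"`` descriptor (D = 64) provides a deterministic, fully
offline stand-in whose components — color histograms, intensity moments,
gradient statistics, a radial intensity profile and co-occurrence texture
— separate the phase-typical appearances of the synthetic phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops

HANDCRAFTED_DIM = 64


@dataclass(frozen=True)
class ExtractorConfig:
    backend: str = "handcrafted"
    dim: int = HANDCRAFTED_DIM  # 1536 is typical for the external ViT backend
    average_pool: bool = True

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("feature dimension must be positive")


ExtractorFn = Callable[[np.ndarray, ExtractorConfig], np.ndarray]
_EXTRACTORS: dict[str, ExtractorFn] = {}


def register_extractor(name: str, fn: ExtractorFn) -> None:
    _EXTRACTORS[name] = fn


def extract_features(patches, config: ExtractorConfig | None = None) -> np.ndarray:
    """Map a list of 64x64 RGB patches to an (N, D) feature matrix.

    Pure function of its inputs: identical patches map to identical rows
    and repeated calls agree bit-for-bit.
    """
    config = config or ExtractorConfig()
    if config.backend == "handcrafted":
        fn = lambda p, c: handcrafted_descriptor(p)
    else:
        fn = _EXTRACTORS.get(config.backend)
        if fn is None:
            raise KeyError(
                f"unknown feature backend {config.backend!r}; "
                f"registered: {sorted(_EXTRACTORS)} + ['handcrafted']"
            )
    rows = []
    for patch in patches:
        patch = np.asarray(patch)
        if patch.shape != (64, 64, 3):
            raise ValueError(f"expected (64, 64, 3) patches, got {patch.shape}")
        rows.append(np.asarray(fn(patch, config), dtype=np.float64))
    if not rows:
        return np.zeros((0, config.dim))
    out = np.vstack(rows)
    if out.shape[1] != config.dim:
        raise ValueError(f"backend produced D={out.shape[1]}, config says {config.dim}")
    return out


def handcrafted_descriptor(patch: np.ndarray) -> np.ndarray:
    """64-dimensional handcrafted descriptor of a 64x64 RGB patch.

    Layout (45 informative components, zero-padded to 64):

    * 0–23   per-channel 8-bin intensity histograms, L1-normalized
    * 24–29  per-channel mean and standard deviation (scaled to [0, 1])
    * 30–32  gradient-magnitude mean, std and 16-bin entropy (nats)
    * 33–40  radial mean-intensity profile on 8 concentric rings
    * 41–44  co-occurrence contrast and homogeneity at offsets right/down
    * 45–54  center-focus block: RGB mean and std inside radius 10 of the
             patch center, RGB mean on the 10–20 annulus, and the mean
             gray level inside radius 4 (the crop is centered on the cell
             being classified, so these give the central cell more weight
             than the global statistics do)

    Histogram, radial and center-focus components are invariant to
    90-degree rotations by construction; gradient statistics vanish on
    constant patches.
    """
    patch = np.asarray(patch)
    if patch.shape != (64, 64, 3):
        raise ValueError(f"expected a (64, 64, 3) patch, got {patch.shape}")
    img = patch.astype(np.float64) / 255.0
    out = np.zeros(HANDCRAFTED_DIM)

    # per-channel histograms (8 bins over [0, 1])
    for ch in range(3):
        hist, _ = np.histogram(img[:, :, ch], bins=8, range=(0.0, 1.0))
        out[ch * 8 : (ch + 1) * 8] = hist / hist.sum()

    # per-channel mean / std
    out[24:27] = img.mean(axis=(0, 1))
    out[27:30] = img.std(axis=(0, 1))

    # gradient-magnitude statistics on the grayscale image
    gray = rgb2gray(patch)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gy, gx)
    out[30] = mag.mean()
    out[31] = mag.std()
    if mag.max() > 0:
        gh, _ = np.histogram(mag, bins=16, range=(0.0, float(mag.max())))
        p = gh / gh.sum()
        p = p[p > 0]
        out[32] = float(-(p * np.log(p)).sum())

    # radial profile: mean gray level in 8 rings around the patch center
    yy, xx = np.indices((64, 64))
    dist = np.hypot(yy - 31.5, xx - 31.5)
    edges = np.linspace(0.0, dist.max() + 1e-9, 9)
    ring = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, 7)
    for k in range(8):
        sel = ring == k
        out[33 + k] = gray[sel].mean() if sel.any() else 0.0

    # co-occurrence texture at 2 offsets (levels quantized to 8)
    q = (gray * 255).astype(np.uint8) // 32
    glcm = graycomatrix(q, distances=[1], angles=[0.0, np.pi / 2], levels=8, normed=True)
    contrast = graycoprops(glcm, "contrast")[0]      # scale: [0, 49]
    homogeneity = graycoprops(glcm, "homogeneity")[0]
    out[41:43] = contrast / 49.0
    out[43:45] = homogeneity

    # center-focus block (crops are centered on the cell of interest)
    center = dist <= 10.0
    annulus = (dist > 10.0) & (dist <= 20.0)
    out[45:48] = img[center].mean(axis=0)
    out[48:51] = img[center].std(axis=0)
    out[51:54] = img[annulus].mean(axis=0)
    out[54] = gray[dist <= 4.0].mean()
    return out
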