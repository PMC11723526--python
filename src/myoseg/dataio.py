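"""Preprocessing and I/O: channel normalisation and stacking, 512x512
patching, right-angle rotation augmentation, label construction, and
tiling/stitching for full-image inference.

Training images are min-max normalised per channel, stacked as
(2, H, W) float grids in [0, 1] (channel 0 = myotube stain, channel 1 =
nuclei stain), and cut into non-overlapping 512x512 patches; each patch is
additionally rotated by 90/180/270 degrees, quadrupling the patch count.
Labels are either taken from synthetic ground truth or bootstrapped from
the raw channels by Otsu thresholding with component centroids standing in
for manually dotted nucleus centres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceImage",
    "Patch",
    "LabelTriple",
    "normalize_and_stack",
    "crop_patches",
    "augment_rotations",
    "make_labels_from_truth",
    "make_labels_from_raw",
    "dilate_centroids",
    "tile_for_inference",
    "stitch",
    "read_image",
    "read_mask",
    "write_mask",
]

PATCH_SIZE = 512  # training patch side used throughout
CENTROID_DILATION_PX = 2  # radius applied to point targets for BCE training


@dataclass
class FluorescenceImage:
    """Two-channel float image in [0,1]; channel 0 myotube, channel 1 nuclei."""

    pixels: np.ndarray  # (2, H, W) float32
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 2:
            raise ValueError(f"expected (2, H, W) pixels, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class Patch:
    pixels: np.ndarray  # (2, s, s)
    origin: tuple[int, int]
    rotation: int = 0  # degrees CCW, one of {0, 90, 180, 270}
    labels: "LabelTriple | None" = None


@dataclass
class LabelTriple:
    """Binary {0,1} targets: myotube mask, nuclei mask, centroid map."""

    myotube: np.ndarray
    nuclei: np.ndarray
    centroid: np.ndarray

    def __post_init__(self):
        for name in ("myotube", "nuclei", "centroid"):
            m = np.asarray(getattr(self, name))
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} labels must contain only {{0,1}}")
            setattr(self, name, m.astype(np.uint8))

    def as_tuple(self):
        return (self.myotube, self.nuclei, self.centroid)


# ---------------------------------------------------------------------------
# normalisation & patching
# ---------------------------------------------------------------------------

def normalize_and_stack(myotube_raw, nuclei_raw, meta=None) -> FluorescenceImage:
    """Per-channel min-max normalisation to [0,1]; constant channels map to 0."""
    a = np.asarray(myotube_raw, dtype=np.float64)
    b = np.asarray(nuclei_raw, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: myotube {a.shape} vs nuclei {b.shape}")

    def _mm(x):
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x, dtype=np.float32)
        return ((x - lo) / (hi - lo)).astype(np.float32)

    return FluorescenceImage(np.stack([_mm(a), _mm(b)]), meta=dict(meta or {}))


def crop_patches(image, size: int = PATCH_SIZE, labels: LabelTriple | None = None) -> list[Patch]:
    """Non-overlapping grid tiling in row-major order (training path)."""
    px = image.pixels if isinstance(image, FluorescenceImage) else np.asarray(image)
    _, h, w = px.shape
    if h % size or w % size:
        raise ValueError(
            f"image ({h}x{w}) not divisible by patch size {size}; "
            "use tile_for_inference for arbitrary sizes"
        )
    out = []
    for r in range(0, h, size):
        for c in range(0, w, size):
            lab = None
            if labels is not None:
                lab = LabelTriple(*(m[r : r + size, c : c + size] for m in labels.as_tuple()))
            out.append(Patch(px[:, r : r + size, c : c + size], origin=(r, c), labels=lab))
    return out


def augment_rotations(patches: list[Patch]) -> list[Patch]:
    """Originals plus 90/180/270-degree CCW rotations (labels rotated alike)."""
    out = []
    for p in patches:
        if p.pixels.shape[-2] != p.pixels.shape[-1]:
            raise ValueError(f"rotation augmentation needs square patches, got {p.pixels.shape}")
        for k in range(4):
            if k == 0:
                out.append(p)
                continue
            lab = None
            if p.labels is not None:
                lab = LabelTriple(*(np.rot90(m, k) for m in p.labels.as_tuple()))
            out.append(
                Patch(np.rot90(p.pixels, k, axes=(1, 2)), origin=p.origin, rotation=90 * k, labels=lab)
            )
    return out


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def make_labels_from_truth(gt) -> LabelTriple:
    """Synthetic ground truth passes straight through (stands in for the
    manual correction step of hand-labelled data)."""
    return LabelTriple(gt.myotube_mask.copy(), gt.nuclei_mask.copy(), gt.centroid_mask.copy())


def _otsu_mask(channel) -> np.ndarray:
    channel = np.asarray(channel)
    if channel.min() == channel.max():
        logger.warning("constant channel: Otsu undefined, returning empty mask")
        return np.zeros(channel.shape, np.uint8)
    t = threshold_otsu(channel)
    mask = (channel > t).astype(np.uint8)
    if not mask.any():
        logger.warning("empty foreground after Otsu threshold %.4g", t)
    return mask


def make_labels_from_raw(image) -> LabelTriple:
    """Automated label bootstrap: per-channel Otsu masks plus one centroid
    pixel per connected nucleus component."""
    px = image.pixels if isinstance(image, FluorescenceImage) else np.asarray(image)
    myo = _otsu_mask(px[0])
    nuc = _otsu_mask(px[1])
    centroid = np.zeros_like(nuc)
    lab, n = ndi.label(nuc)
    if n:
        for r, c in ndi.center_of_mass(nuc, lab, range(1, n + 1)):
            centroid[int(round(r)), int(round(c))] = 1
    return LabelTriple(myo, nuc, centroid)


def dilate_centroids(centroid_mask, radius: int = CENTROID_DILATION_PX) -> np.ndarray:
    """Thicken single-pixel centroid targets (point targets make BCE learning
    degenerate); predictions are thinned back to points downstream."""
    if radius <= 0:
        return np.asarray(centroid_mask, np.uint8)
    return ndi.binary_dilation(
        np.asarray(centroid_mask, bool), structure=disk(radius).astype(bool)
    ).astype(np.uint8)


# ---------------------------------------------------------------------------
# inference tiling
# ---------------------------------------------------------------------------

def _tile_starts(dim: int, size: int, step: int) -> list[int]:
    starts = list(range(0, dim - size + 1, step))
    if starts[-1] + size < dim:
        starts.append(dim - size)
    return starts


def tile_for_inference(image, size: int = PATCH_SIZE, overlap: int = 0):
    """Cover the image with possibly-overlapping tiles; returns (tiles, origins)."""
    px = image.pixels if isinstance(image, FluorescenceImage) else np.asarray(image)
    if px.ndim == 2:
        px = px[None]
    _, h, w = px.shape
    if overlap < 0 or overlap >= size:
        raise ValueError(f"overlap must be in [0, size), got {overlap}")
    if size > h or size > w:
        raise ValueError(f"tile size {size} exceeds image ({h}x{w})")
    step = size - overlap
    tiles, origins = [], []
    for r in _tile_starts(h, size, step):
        for c in _tile_starts(w, size, step):
            tiles.append(px[:, r : r + size, c : c + size])
            origins.append((r, c))
    return tiles, origins


def stitch(tiles, origins, height: int, width: int) -> np.ndarray:
    """Reassemble tiles by per-pixel averaging of all covering tiles."""
    if len(tiles) != len(origins):
        raise ValueError(f"{len(tiles)} tiles but {len(origins)} origins")
    t0 = np.asarray(tiles[0])
    c = t0.shape[0] if t0.ndim == 3 else 1
    acc = np.zeros((c, height, width), np.float64)
    cnt = np.zeros((height, width), np.float64)
    for t, (r, co) in zip(tiles, origins):
        t = np.asarray(t)
        if t.ndim == 2:
            t = t[None]
        s1, s2 = t.shape[-2:]
        acc[:, r : r + s1, co : co + s2] += t
        cnt[r : r + s1, co : co + s2] += 1
    if (cnt == 0).any():
        raise ValueError("tiles do not cover the full image")
    out = (acc / cnt).astype(np.float32)
    return out if t0.ndim == 3 else out[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG channel or multi-page stack as a raw intensity array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def read_mask(path) -> np.ndarray:
    """Read a {0,255} PNG mask as {0,1} uint8."""
    m = read_image(path)
    return (np.asarray(m) > 0).astype(np.uint8)


def write_mask(path, mask) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * np.uint8(255))
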