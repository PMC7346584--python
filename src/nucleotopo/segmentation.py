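"""Nucleus and signal segmentation for schematic FISH / AgNOR rasters.

The upstream microscope software reduces a multi-color acquisition to a
schematic image in which nucleus, signals and background carry distinct
colors; this module recovers the objects from such rasters.

Channel conventions:

* nucleus   — red channel for FISH/PI-stained images, inverted luminance
              for bright-field Ag-stained images;
* ``fish``  — green channel inside the nucleus mask;
* ``agnor`` — either the inverted luminance (silver-stained nucleoli are
              dark on a light nucleus) or the red channel (PI-saturated
              nucleoli in FISH images), selected by ``agnor_polarity``.

Thresholds default to Otsu's criterion computed on the within-mask
histogram (parameter-free for bimodal schematic images); a fixed value
can be forced through the config.  Connected components are 8-connected;
components closer than ``merge_gap`` pixels are reunited to undo
fragmentation of a single signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = [
    "SegmentationConfig",
    "SignalBlob",
    "NoNucleusError",
    "segment_nucleus",
    "detect_signals",
    "count_agnor",
]


class NoNucleusError(ValueError):
    """Raised when no sufficiently large foreground component exists."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation stage (JSON-serializable)."""

    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 128.0
    min_area: int = 5  # px; smaller signal components are dropped
    merge_gap: int = 2  # px; components closer than this are merged
    agnor_polarity: str = "bright_red"  # "bright_red" (FISH/PI) | "dark" (Ag)
    image_style: str = "fish"  # "fish" | "agnor"
    min_nucleus_area: int = 200  # px

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.agnor_polarity not in ("bright_red", "dark"):
            raise ValueError(f"unknown agnor_polarity {self.agnor_polarity!r}")
        if self.image_style not in ("fish", "agnor"):
            raise ValueError(f"unknown image_style {self.image_style!r}")


@dataclass
class SignalBlob:
    """One detected connected component inside the nucleus."""

    label: int
    channel: str
    centroid: tuple[float, float]  # (x, y), intensity-weighted
    area_px: int
    pixels: np.ndarray  # (m, 2) int, (y, x)
    boundary: np.ndarray  # (k, 2) float, (x, y)

    def pixel_set(self) -> set[tuple[int, int]]:
        """Blob pixels as a set of (x, y) tuples (point-in-blob tests)."""
        return {(int(x), int(y)) for y, x in self.pixels}


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    if img.shape[0] < 16 or img.shape[1] < 16:
        raise ValueError("image dimensions must be >= 16 px")
    return img.astype(float)


def _nucleus_channel(img: np.ndarray, style: str) -> np.ndarray:
    if style == "fish":
        return img[:, :, 0]
    return 255.0 - img.mean(axis=2)  # Ag: dark nucleus on light background


def _signal_channel(img: np.ndarray, channel: str, cfg: SegmentationConfig) -> np.ndarray:
    if channel == "fish":
        return img[:, :, 1]
    if channel == "agnor":
        if cfg.agnor_polarity == "bright_red":
            return img[:, :, 0]
        return 255.0 - img.mean(axis=2)
    raise ValueError(f"unknown channel {channel!r}")


def segment_nucleus(
    img: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()
) -> tuple[np.ndarray, bool]:
    """Binary nucleus mask: largest thresholded component, holes filled.

    Returns ``(mask, border_flag)``; the flag marks masks touching the
    image border (such nuclei are excluded from analysis downstream).
    Raises :class:`NoNucleusError` if no component reaches
    ``min_nucleus_area`` pixels.
    """
    img = _validate_image(img)
    chan = _nucleus_channel(img, cfg.image_style)
    if chan.max() - chan.min() < 1.0:
        raise NoNucleusError("no nucleus found: image has no contrast")
    if cfg.threshold_mode == "fixed":
        thr = cfg.fixed_threshold
    elif cfg.image_style == "agnor":
        # Bright-field Ag histograms are trimodal (background, nucleus,
        # dark nucleolar spots); the nucleus is everything above the
        # background/nucleus split of a 3-class Otsu.
        from skimage.filters import threshold_multiotsu

        thr = threshold_multiotsu(chan, classes=3)[0]
    else:
        thr = threshold_otsu(chan)
    binary = ndi.binary_fill_holes(chan > thr)
    labels, n = cc_label(binary, connectivity=2, return_num=True)
    if n == 0:
        raise NoNucleusError("no nucleus found: empty foreground")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_nucleus_area:
        raise NoNucleusError(
            f"no nucleus found: largest component {sizes[best - 1]} px "
            f"< {cfg.min_nucleus_area} px"
        )
    mask = labels == best
    border = bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())
    return mask, border


def _boundary_pixels(blob_mask: np.ndarray) -> np.ndarray:
    """(x, y) coordinates of blob pixels adjacent to the outside."""
    interior = ndi.binary_erosion(blob_mask, structure=np.ones((3, 3)))
    ys, xs = np.nonzero(blob_mask & ~interior)
    return np.stack([xs, ys], axis=1).astype(float)


def detect_signals(
    img: np.ndarray,
    mask: np.ndarray,
    channel: str = "fish",
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[SignalBlob]:
    """Threshold ``channel`` inside the nucleus mask and extract blobs.

    8-connected components; components below ``min_area`` are dropped;
    components whose boundary gap is at most ``merge_gap`` pixels are
    merged back into one signal.  Blobs are returned sorted by area,
    descending.  An empty list is a valid result.
    """
    img = _validate_image(img)
    mask = np.asarray(mask, dtype=bool)
    chan = _signal_channel(img, channel, cfg)
    vals = chan[mask]
    if vals.size == 0:
        return []
    if cfg.threshold_mode == "fixed":
        thr = cfg.fixed_threshold
    else:
        if vals.max() - vals.min() < 1.0:
            return []  # single mode: nothing to separate
        thr = threshold_otsu(vals)
    binary = (chan > thr) & mask
    if not binary.any():
        return []
    if cfg.merge_gap > 0:
        radius = int(np.ceil(cfg.merge_gap / 2))
        merged = ndi.binary_dilation(binary, structure=disk(radius))
    else:
        merged = binary
    labels = cc_label(merged, connectivity=2)
    labels = labels * binary  # merged labels restricted to real pixels
    blobs: list[SignalBlob] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        blob_mask = labels == lab
        area = int(blob_mask.sum())
        if area < cfg.min_area:
            continue
        ys, xs = np.nonzero(blob_mask)
        w = chan[ys, xs]
        w = w / w.sum()
        blobs.append(
            SignalBlob(
                label=0,  # reassigned after sorting
                channel=channel,
                centroid=(float(np.sum(xs * w)), float(np.sum(ys * w))),
                area_px=area,
                pixels=np.stack([ys, xs], axis=1),
                boundary=_boundary_pixels(blob_mask),
            )
        )
    blobs.sort(key=lambda b: -b.area_px)
    for i, b in enumerate(blobs):
        b.label = i + 1
    return blobs


def count_agnor(blobs: list[SignalBlob]) -> int:
    """AgNOR copy number: the count of retained nucleolar blobs."""
    return len(blobs)
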