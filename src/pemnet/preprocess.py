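"""Rule-based mammogram preprocessing: breast extraction and orientation.

The chain aligns the pectoral wall to the left edge and crops the breast:

1. orientation test - the pectoral wall is on the left when the non-zero
   pixel count of the left half is at least that of the right half;
2. horizontal flip of right-oriented images;
3. binarisation at a fixed gray threshold (default 20 on the 8-bit scale,
   strict inequality);
4. largest connected component (default 8-connectivity) as the breast mask;
5. morphological opening with a disk (default radius 5 px) to drop small
   bright objects such as labels or acquisition artefacts;
6. tight crop of image and mask to the mask's bounding box.

Coordinates are 0-based, row-major, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_opening
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .view import classify_view, train_view_classifier  # noqa: F401  (part of
# the preprocessing surface: view classification decides which images are
# MLO and therefore need pectoral segmentation)

__all__ = ["Mammogram", "PrepResult", "normalize_to_8bit", "detect_orientation",
           "flip_to_left", "binarize", "largest_component", "morphological_open",
           "crop_to_bbox", "extract_breast", "read_image",
           "train_view_classifier", "classify_view"]

LEFT, RIGHT = "left", "right"


@dataclass
class Mammogram:
    """An 8-bit grayscale mammogram (values in [0, 255])."""

    pixels: np.ndarray
    provenance: str = "array"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Mammogram requires a non-empty 2-D pixel grid")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("Mammogram pixel values must lie in [0, 255]")


@dataclass
class PrepResult:
    """Cropped breast image plus the mask, orientation and bounding box."""

    image: Mammogram
    breast_mask: np.ndarray             # binary, cropped frame
    orientation: str                    # orientation detected on the input
    bbox: tuple[int, int, int, int]     # (row0, col0, row1, col1) half-open,
                                        # in the flipped full frame


def _as_2d(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, Mammogram) else np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def normalize_to_8bit(raw: np.ndarray, provenance: str = "array") -> Mammogram:
    """Linear min-max rescale of any integer bit depth to [0, 255].

    Constant images map to all zeros (degenerate range).
    """
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("cannot normalise an empty image")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return Mammogram(np.zeros(raw.shape, dtype=np.uint8), provenance)
    scaled = np.rint((raw.astype(np.float64) - lo) * (255.0 / (hi - lo)))
    return Mammogram(scaled.astype(np.uint8), provenance)


def detect_orientation(img) -> str:
    """'left' iff the left half has at least as many non-zero pixels."""
    arr = _as_2d(img)
    if arr.shape[1] < 2:
        raise ValueError("orientation detection requires width >= 2")
    half = arr.shape[1] // 2
    left_count = np.count_nonzero(arr[:, :half])
    right_count = np.count_nonzero(arr[:, half:])
    return LEFT if left_count >= right_count else RIGHT


def flip_to_left(img, orientation: str):
    """Mirror horizontally when the detected orientation is 'right'."""
    arr = _as_2d(img)
    out = arr[:, ::-1].copy() if orientation == RIGHT else arr
    if isinstance(img, Mammogram):
        return Mammogram(out, img.provenance)
    return out


def binarize(img, threshold: float = 20) -> np.ndarray:
    """Foreground iff pixel value is strictly greater than the threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return _as_2d(img) > threshold


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected foreground component.

    Size ties resolve to the component whose label comes first in
    raster-scan order.  An empty mask stays empty.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    labels = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def morphological_open(mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Binary opening (erosion then dilation) with a disk footprint.

    Pixels outside the frame count as background, so foreground touching
    the border erodes like any other boundary.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mask = np.asarray(mask).astype(bool)
    if radius == 0:
        return mask.copy()
    return binary_opening(mask, structure=disk(radius))


def crop_to_bbox(img, mask: np.ndarray):
    """Tight half-open bounding-box crop of image and mask together."""
    arr = _as_2d(img)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("no breast found: mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    r0, c0, r1, c1 = bbox
    return arr[r0:r1, c0:c1], mask[r0:r1, c0:c1], bbox


def extract_breast(img, threshold: float = 20, radius: int = 5,
                   connectivity: int = 8) -> PrepResult:
    """Full chain: orient, flip, binarise, largest component, open, crop."""
    arr = _as_2d(img)
    orientation = detect_orientation(arr)
    flipped = flip_to_left(arr, orientation)
    mask = binarize(flipped, threshold)
    mask = largest_component(mask, connectivity)
    mask = morphological_open(mask, radius)
    crop, mask_crop, bbox = crop_to_bbox(flipped, mask)
    provenance = img.provenance if isinstance(img, Mammogram) else "array"
    return PrepResult(image=Mammogram(crop, provenance),
                      breast_mask=mask_crop, orientation=orientation, bbox=bbox)


def embed_in_frame(result: PrepResult, shape: tuple[int, int]) -> np.ndarray:
    """Re-embed the cropped breast mask into the flipped full frame."""
    full = np.zeros(shape, dtype=bool)
    r0, c0, r1, c1 = result.bbox
    full[r0:r1, c0:c1] = result.breast_mask
    return full


def read_image(path) -> Mammogram:
    """Read an 8/16-bit grayscale PNG, or a DICOM file, normalised to 8-bit."""
    path = str(path)
    if path.lower().endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(path)
        return normalize_to_8bit(ds.pixel_array, provenance=path)
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("I"))
    if arr.max() > 255:
        return normalize_to_8bit(arr, provenance=path)
    return Mammogram(arr.astype(np.uint8), provenance=path)
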